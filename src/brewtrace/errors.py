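"""Exception hierarchy shared across the package."""


class BrewtraceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BrewtraceError):
    """A file did not conform to its declared format."""


class PloidyConflictError(BrewtraceError):
    """A strain mixes genotype arities across VCF records."""

    def __init__(self, strain: str, chrom: str, pos: int, seen: int, expected: int):
        self.strain = strain
        self.chrom = chrom
        self.pos = pos
        super().__init__(
            f"strain {strain!r} has ploidy {seen} at {chrom}:{pos + 1} "
            f"but ploidy {expected} elsewhere"
        )


class ConfigurationError(BrewtraceError):
    """A required annotation/column/parameter is absent or invalid."""


class SinglePeakError(BrewtraceError):
    """A fluorescence density has only one mode; carries that mode."""

    def __init__(self, mode: float):
        self.mode = mode
        super().__init__(f"only one density peak found (at {mode:g})")


class UndeterminedPloidyError(BrewtraceError):
    """No allele-frequency mode could be matched to a ploidy."""
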