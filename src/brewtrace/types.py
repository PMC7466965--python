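"""Tabular domain objects shared by the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brewtrace.errors import BrewtraceError

SV_CLASSES = (
    "deletion",
    "insertion",
    "tandem_duplication",
    "interspersed_duplication",
    "inversion",
)


@dataclass
class CoverageTrack:
    """Per-strain normalized read depth in fixed-width genomic windows.

    ``windows`` columns: chrom, start, end, value. A value of 1.0 corresponds
    to the strain's baseline ploidy.
    """

    strain: str
    windows: pd.DataFrame
    window_size: int = 250
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        w = self.windows
        if len(w) == 0:
            raise BrewtraceError("empty coverage track")
        if (w["value"] < 0).any():
            raise BrewtraceError("negative coverage values")
        self.windows = w.sort_values(["chrom", "start"]).reset_index(drop=True)
        if not self.chrom_lengths:
            self.chrom_lengths = self.windows.groupby("chrom")["end"].max().to_dict()

    def values_on(self, chrom: str) -> np.ndarray:
        return self.windows.loc[self.windows["chrom"] == chrom, "value"].to_numpy()


@dataclass
class SVCallSet:
    """Typed structural-variant calls for one strain.

    ``calls`` columns: chrom, pos, svclass, support.
    """

    strain: str
    depth: float
    calls: pd.DataFrame

    def __post_init__(self):
        bad = set(self.calls["svclass"]) - set(SV_CLASSES)
        if bad:
            raise BrewtraceError(f"unknown SV classes: {sorted(bad)}")
        if (self.calls["support"] < 0).any():
            raise BrewtraceError("negative read support")

    def of_class(self, svclass: str) -> pd.DataFrame:
        return self.calls[self.calls["svclass"] == svclass]


@dataclass
class SplitReadSet:
    """Long-read alignment segment records.

    ``records`` columns: read_id, read_len, read_start, read_end, chrom,
    start, end, strand, flag (primary/supplementary/secondary).
    """

    records: pd.DataFrame
    genome_length: int
    total_read_bases: int

    def __post_init__(self):
        bad = set(self.records["flag"]) - {"primary", "supplementary", "secondary"}
        if bad:
            raise BrewtraceError(f"unknown alignment flags: {sorted(bad)}")

    @property
    def depth(self) -> float:
        return self.total_read_bases / self.genome_length


@dataclass
class GrowthCurve:
    """Time-ordered optical-density readings for one well."""

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) < 5:
            raise BrewtraceError("growth curve needs at least 5 timepoints")
        if not (np.diff(self.times) > 0).all():
            raise BrewtraceError("times must be strictly increasing")


@dataclass
class FluorescenceSample:
    """Per-cell fluorescence intensities for one strain."""

    values: np.ndarray
    strain: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values <= 0).any():
            raise BrewtraceError("fluorescence values must be positive")
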