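"""Genome sequences, annotated intervals and coordinate lift-over maps."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from brewtrace.errors import BrewtraceError, FormatError

FEATURE_KINDS = {"gene", "repeat_element", "cds"}


@dataclass(frozen=True)
class Feature:
    """Annotated interval on a chromosome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"
    id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise BrewtraceError(
                f"invalid feature interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise BrewtraceError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """BED-like record: (chrom, start, end, label, value)."""

    chrom: str
    start: int
    end: int
    label: str = ""
    value: float = 0.0

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise BrewtraceError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Ordered collection of :class:`Interval` records."""

    def __init__(self, records: Iterable[Interval] = ()):
        self.records: list[Interval] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.records == other.records

    def on(self, chrom: str) -> list[Interval]:
        return [r for r in self.records if r.chrom == chrom]

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.records, key=lambda r: (r.chrom, r.start)))


class GenomeModel:
    """Chromosome sequences (or bare lengths) plus interval features.

    Parameters
    ----------
    chromosomes:
        Ordered mapping or list of ``(name, sequence-or-length)`` pairs.
    features:
        Iterable of :class:`Feature`; each must fit inside its chromosome.
    """

    def __init__(
        self,
        chromosomes: Union[dict, Iterable[tuple]],
        features: Iterable[Feature] = (),
    ):
        if isinstance(chromosomes, dict):
            chromosomes = chromosomes.items()
        self.sequences: dict[str, Optional[str]] = {}
        self.lengths: dict[str, int] = {}
        for name, payload in chromosomes:
            if isinstance(payload, int):
                self.sequences[name] = None
                self.lengths[name] = payload
            else:
                seq = str(payload).upper()
                self.sequences[name] = seq
                self.lengths[name] = len(seq)
        self.features: list[Feature] = []
        for feat in features:
            self.add_feature(feat)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def add_feature(self, feat: Feature) -> None:
        if feat.chrom not in self.lengths:
            raise BrewtraceError(f"feature on unknown chromosome {feat.chrom!r}")
        if feat.end > self.lengths[feat.chrom]:
            raise BrewtraceError(
                f"feature {feat.id or feat.kind} exceeds chromosome "
                f"{feat.chrom} ({feat.end} > {self.lengths[feat.chrom]})"
            )
        self.features.append(feat)

    def sequence(self, chrom: str) -> str:
        seq = self.sequences.get(chrom)
        if seq is None:
            raise BrewtraceError(f"no sequence stored for chromosome {chrom!r}")
        return seq

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeModel)
            and self.sequences == other.sequences
            and self.lengths == other.lengths
            and sorted(self.features, key=lambda f: (f.chrom, f.start, f.id))
            == sorted(other.features, key=lambda f: (f.chrom, f.start, f.id))
        )


@dataclass(frozen=True)
class MapBlock:
    """Collinear block: src [start, end) maps onto dst_chrom at dst_start."""

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    strand: str = "+"


class CoordinateMap:
    """Piecewise-collinear map between two genomes (plus strand only).

    Used as the truth map from a rearranged genome back to its reference.
    """

    def __init__(self, blocks: Iterable[MapBlock] = ()):
        self.blocks: list[MapBlock] = sorted(
            blocks, key=lambda b: (b.src_chrom, b.src_start)
        )

    @classmethod
    def identity(cls, genome: GenomeModel) -> "CoordinateMap":
        return cls(
            MapBlock(name, 0, length, name, 0)
            for name, length in genome.lengths.items()
        )

    def map_interval(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[int, int, str, int, int]]:
        """Project src interval; returns (src_s, src_e, dst_chrom, dst_s, dst_e)."""
        out = []
        for b in self.blocks:
            if b.src_chrom != chrom:
                continue
            lo, hi = max(start, b.src_start), min(end, b.src_end)
            if lo >= hi:
                continue
            off = b.dst_start - b.src_start
            out.append((lo, hi, b.dst_chrom, lo + off, hi + off))
        return out

    def map_point(self, chrom: str, pos: int) -> tuple[str, int]:
        hits = self.map_interval(chrom, pos, pos + 1)
        if not hits:
            raise BrewtraceError(f"position {chrom}:{pos} not covered by map")
        _, _, dst_chrom, dst_s, _ = hits[0]
        return dst_chrom, dst_s

    def compose(self, outer: "CoordinateMap") -> "CoordinateMap":
        """Return self ∘ outer applied after: src --self--> mid --outer--> dst."""
        blocks = []
        for b in self.blocks:
            for lo, hi, dchrom, ds, _de in outer.map_interval(
                b.dst_chrom, b.dst_start, b.dst_start + (b.src_end - b.src_start)
            ):
                src_lo = b.src_start + (lo - b.dst_start)
                blocks.append(
                    MapBlock(b.src_chrom, src_lo, src_lo + (hi - lo), dchrom, ds)
                )
        return CoordinateMap(blocks)


# ---------------------------------------------------------------------------
# FASTA / BED


def read_fasta(path: Union[str, Path], features: Iterable[Feature] = ()) -> GenomeModel:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeModel([(r.id, str(r.seq)) for r in records], features)


def write_fasta(genome: GenomeModel, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(name)), id=name, description="")
        for name in genome.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: Union[str, Path]) -> IntervalSet:
    """Read BED4-6; column 5 (score) is parsed into ``value`` when present."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            value = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            records.append(Interval(chrom, start, end, label, value))
    return IntervalSet(records)


def write_bed(intervals: IntervalSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in intervals:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label or '.'}\t{r.value:g}\t+\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
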