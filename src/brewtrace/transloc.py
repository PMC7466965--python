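"""Interchromosomal translocation detection from split long-read mappings,
and a detection power study at repeat vs genic breakpoints."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from brewtrace.core_io.genome import GenomeModel, Interval
from brewtrace.errors import BrewtraceError
from brewtrace.synthetic_data import (
    ReadSimConfig,
    apply_translocations,
    demote_repeat_segments,
    simulate_long_reads,
)
from brewtrace.types import SplitReadSet

BIN_SIZE = 20_000

BinPair = tuple[tuple[str, int], tuple[str, int]]


def _canonical(a: tuple[str, int], b: tuple[str, int]) -> BinPair:
    return (a, b) if a <= b else (b, a)


def select_split_reads(reads: SplitReadSet) -> SplitReadSet:
    """Keep reads with >=1 supplementary and no secondary mapping whose
    records span exactly two distinct chromosomes."""
    rec = reads.records
    by_read = rec.groupby("read_id")
    keep_ids = []
    for rid, grp in by_read:
        flags = grp["flag"]
        if (flags == "secondary").any():
            continue
        if not (flags == "supplementary").any():
            continue
        if grp["chrom"].nunique() != 2:
            continue
        keep_ids.append(rid)
    kept = rec[rec["read_id"].isin(keep_ids)].reset_index(drop=True)
    return SplitReadSet(kept, reads.genome_length, reads.total_read_bases)


@dataclass
class ContactMatrix:
    """Split-read counts between 20 kb bins on different chromosomes."""

    bin_size: int = BIN_SIZE
    depth: float = 0.0
    entries: dict = field(default_factory=dict)  # BinPair -> read count

    @property
    def total_reads(self) -> int:
        return int(sum(self.entries.values()))

    def fraction(self, key: BinPair) -> float:
        return self.entries.get(key, 0) / self.depth if self.depth > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromA": a[0], "binA": a[1], "chromB": b[0], "binB": b[1],
                "read_count": c, "fraction": self.fraction(((a), (b))),
            }
            for (a, b), c in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["chromA", "binA", "chromB", "binB", "read_count", "fraction"],
        )


def contact_matrix(reads: SplitReadSet, bin_size: int = BIN_SIZE) -> ContactMatrix:
    """One count per selected read, at the bin pair of the midpoints of its
    longest segment on each of its two chromosomes. The genome-wide depth
    D = total_read_bases / genome_length converts counts to approximate
    haplotype fractions."""
    depth = reads.depth
    entries: dict[BinPair, int] = {}
    rec = reads.records
    if len(rec):
        rec = rec.assign(_seglen=rec["end"] - rec["start"])
        for rid, grp in rec.groupby("read_id"):
            chroms = grp["chrom"].unique()
            if len(chroms) != 2:
                raise BrewtraceError(
                    f"read {rid} spans {len(chroms)} chromosomes; run "
                    "select_split_reads first"
                )
            bins = []
            for chrom in chroms:
                seg = grp[grp["chrom"] == chrom].sort_values("_seglen").iloc[-1]
                mid = (int(seg["start"]) + int(seg["end"])) // 2
                bins.append((str(chrom), mid // bin_size))
            key = _canonical(bins[0], bins[1])
            entries[key] = entries.get(key, 0) + 1
    return ContactMatrix(bin_size=bin_size, depth=depth, entries=entries)


@dataclass
class TranslocationCandidate:
    chromA: str
    binsA: tuple[int, int]  # inclusive bin index range
    chromB: str
    binsB: tuple[int, int]
    read_count: int
    fraction: float

    def covers(self, key: BinPair) -> bool:
        (ca, ba), (cb, bb) = key
        return (
            ca == self.chromA
            and cb == self.chromB
            and self.binsA[0] <= ba <= self.binsA[1]
            and self.binsB[0] <= bb <= self.binsB[1]
        )


def detect_translocations(
    matrix: ContactMatrix,
    min_reads: int = 3,
    min_fraction: float = 0.15,
    control: Optional[ContactMatrix] = None,
) -> list[TranslocationCandidate]:
    """Report bin pairs with read_count >= min_reads and haplotype fraction
    >= min_fraction, excluding pairs present in the control mask; adjacent
    significant pairs (same chromosome pair, bin offset <= 1 on both axes)
    are merged into one candidate."""
    mask = set(control.entries) if control is not None else set()
    sig = [
        key
        for key, count in matrix.entries.items()
        if key not in mask
        and count >= min_reads
        and matrix.fraction(key) >= min_fraction
    ]
    # merge adjacent significant bin pairs via connected components
    remaining = set(sig)
    candidates = []
    while remaining:
        seed_key = remaining.pop()
        component = {seed_key}
        frontier = [seed_key]
        while frontier:
            (ca, ba), (cb, bb) = frontier.pop()
            neighbours = [
                k
                for k in remaining
                if k[0][0] == ca
                and k[1][0] == cb
                and abs(k[0][1] - ba) <= 1
                and abs(k[1][1] - bb) <= 1
            ]
            for k in neighbours:
                remaining.remove(k)
                component.add(k)
                frontier.append(k)
        chromA = next(iter(component))[0][0]
        chromB = next(iter(component))[1][0]
        bins_a = [k[0][1] for k in component]
        bins_b = [k[1][1] for k in component]
        count = sum(matrix.entries[k] for k in component)
        candidates.append(
            TranslocationCandidate(
                chromA=chromA,
                binsA=(min(bins_a), max(bins_a)),
                chromB=chromB,
                binsB=(min(bins_b), max(bins_b)),
                read_count=count,
                fraction=count / matrix.depth if matrix.depth > 0 else float("nan"),
            )
        )
    candidates.sort(key=lambda c: (c.chromA, c.binsA, c.chromB, c.binsB))
    return candidates


def power_experiment(
    reference: GenomeModel,
    breakpoints: Sequence[tuple[tuple[Interval, Interval], str]],
    read_cfg: ReadSimConfig,
    n_replicates: int = 10,
    seed: int = 0,
    min_reads: int = 3,
    min_fraction: float = 0.15,
    bin_size: int = BIN_SIZE,
    cut: float = 0.5,
) -> dict[str, float]:
    """Detection power of the split-mapping pipeline per breakpoint label.

    Per replicate the reference is rearranged at every breakpoint pair,
    error-free long reads are simulated, segments falling entirely within a
    repeat element with a same-strand homologous copy are demoted to
    secondary (emulating mapping ambiguity), and the select -> bin -> detect
    pipeline is run. A breakpoint counts as detected when a candidate covers
    its true junction bin pair. Returns label -> fraction of replicate
    detections.
    """
    if n_replicates <= 0:
        raise BrewtraceError("n_replicates must be positive")
    derived, truth_map = apply_translocations(
        reference, [pair for pair, _ in breakpoints], cut
    )
    truth_keys = []
    for (bpA, bpB), label in breakpoints:
        cutA = bpA.start + int(round(cut * (bpA.end - bpA.start)))
        cutB = bpB.start + int(round(cut * (bpB.end - bpB.start)))
        truth_keys.append(
            (_canonical((bpA.chrom, cutA // bin_size), (bpB.chrom, cutB // bin_size)),
             label)
        )
    hits = {label: 0 for _, label in breakpoints}
    totals = {label: 0 for _, label in breakpoints}
    for rep in range(n_replicates):
        cfg = ReadSimConfig(
            depth=read_cfg.depth,
            length_mean=read_cfg.length_mean,
            length_sd=read_cfg.length_sd,
            min_len=read_cfg.min_len,
            max_len=read_cfg.max_len,
            seed=seed + rep,
        )
        _, split_reads = simulate_long_reads(derived, truth_map, cfg)
        split_reads = demote_repeat_segments(split_reads, reference)
        selected = select_split_reads(split_reads)
        matrix = contact_matrix(selected, bin_size)
        candidates = detect_translocations(matrix, min_reads, min_fraction)
        for key, label in truth_keys:
            totals[label] += 1
            if any(c.covers(key) for c in candidates):
                hits[label] += 1
    return {label: hits[label] / totals[label] for label in hits}
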