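"""Plain-text tabular readers/writers: bedGraph coverage, SV tables,
PAF-like alignment segments and plate-reader TSVs."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from brewtrace.errors import FormatError
from brewtrace.types import CoverageTrack, GrowthCurve, SplitReadSet, SVCallSet

SPLIT_READ_COLUMNS = [
    "read_id",
    "read_len",
    "read_start",
    "read_end",
    "chrom",
    "start",
    "end",
    "strand",
    "flag",
]


def read_coverage_bedgraph(
    path: Union[str, Path], strain: str = "", window_size: int = 250
) -> CoverageTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].astype(str).str.startswith(("#", "track", "browser"))]
    df = df.astype({"start": int, "end": int, "value": float})
    if len(df) == 0:
        raise FormatError(f"no coverage windows in {path}")
    return CoverageTrack(strain or Path(path).stem, df, window_size)


def write_coverage_bedgraph(track: CoverageTrack, path: Union[str, Path]) -> None:
    track.windows[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def read_sv_table(path: Union[str, Path], strain: str = "", depth: float = 0.0) -> SVCallSet:
    """BED-like TSV with columns chrom, pos, svclass, support (header line)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "svclass", "support"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SV table needs columns {sorted(required)}")
    return SVCallSet(strain or Path(path).stem, depth, df)


def write_sv_table(calls: SVCallSet, path: Union[str, Path]) -> None:
    calls.calls[["chrom", "pos", "svclass", "support"]].to_csv(
        path, sep="\t", index=False
    )


def read_split_reads(
    path: Union[str, Path], genome_length: int, total_read_bases: int = 0
) -> SplitReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    missing = set(SPLIT_READ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: split-read table lacks columns {sorted(missing)}")
    if not total_read_bases:
        total_read_bases = int(
            df.drop_duplicates("read_id")["read_len"].sum()
        )
    return SplitReadSet(df[SPLIT_READ_COLUMNS], genome_length, total_read_bases)


def write_split_reads(reads: SplitReadSet, path: Union[str, Path]) -> None:
    reads.records[SPLIT_READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_growth_table(path: Union[str, Path]) -> dict[str, GrowthCurve]:
    """Plate TSV: a ``time`` column (hours) plus one column per well."""
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise FormatError(f"{path}: plate table needs a 'time' column")
    times = df["time"].to_numpy(dtype=float)
    return {
        well: GrowthCurve(times, df[well].to_numpy(dtype=float), strain=well)
        for well in df.columns
        if well != "time"
    }
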