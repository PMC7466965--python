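"""Read-depth CNV calling and relatedness-pruned frequency estimation.

Works on normalized coverage in fixed 250 bp windows where 1.0 equals the
strain's baseline ploidy. Strains with a sloping coverage artifact toward
chromosome ends are filtered before calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu

from brewtrace.core_io.genome import IntervalSet
from brewtrace.errors import BrewtraceError
from brewtrace.popgen import RelatednessMatrix
from brewtrace.types import CoverageTrack

MIN_SEGMENT_WINDOWS = 40  # 40 x 250 bp = 10 kb
RUN_PURITY = 0.90
SLOPE_LIMIT = 0.15
SMOOTH_WINDOWS = 7
EDGE_SEARCH_WINDOWS = 6


@dataclass
class CNVSegment:
    strain: str
    chrom: str
    start: int
    end: int
    type: str  # gain | loss
    copy_number: int
    p_value: float = float("nan")
    tested: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Divide raw window depth by its genome-wide median (output median = 1)."""
    med = float(track.windows["value"].median())
    if med <= 0:
        raise BrewtraceError("median coverage is zero; cannot normalize")
    windows = track.windows.copy()
    windows["value"] = windows["value"] / med
    return CoverageTrack(track.strain, windows, track.window_size, dict(track.chrom_lengths))


def end_slope(track: CoverageTrack) -> tuple[float, bool]:
    """Chromosome-end coverage slope and the keep/drop decision.

    x is the normalized distance of a window centre from its chromosome
    midpoint (0 at the middle, 1 at an end), pooled across chromosomes;
    y is log2 normalized coverage clamped to [-2, 2] (zero coverage maps to
    -2). OLS slope; the strain is dropped iff b < -0.15 or b > 0.15
    (strictly, so b = ±0.15 keeps).
    """
    xs, ys = [], []
    for chrom, length in track.chrom_lengths.items():
        sub = track.windows[track.windows["chrom"] == chrom]
        centers = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        mid = length / 2.0
        xs.append(np.abs(centers - mid) / mid)
        with np.errstate(divide="ignore"):
            y = np.log2(sub["value"].to_numpy(dtype=float))
        ys.append(np.clip(y, -2.0, 2.0))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    b = float(np.polyfit(x, y, 1)[0])
    eps = 1e-9  # keep the exact ±0.15 boundary robust to fp noise
    keep = not (b < -SLOPE_LIMIT - eps or b > SLOPE_LIMIT + eps)
    return b, keep


def _merge_runs(classes: np.ndarray, target: int) -> list[tuple[int, int]]:
    """Maximal [i, j) stretches starting/ending on `target` windows whose
    purity (fraction of `target`) stays > RUN_PURITY."""
    idx = np.flatnonzero(classes == target)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for k in idx[1:]:
        if k == prev + 1:
            prev = k
            continue
        runs.append((start, prev + 1))
        start = prev = k
    runs.append((start, prev + 1))
    merged = [runs[0]]
    for s, e in runs[1:]:
        ms, me = merged[-1]
        span = e - ms
        pure = int((classes[ms:e] == target).sum())
        if pure / span > RUN_PURITY:
            merged[-1] = (ms, e)
        else:
            merged.append((s, e))
    return merged


def _refine_edges(raw: np.ndarray, i: int, j: int, cn: int, ploidy: int) -> tuple[int, int]:
    """Least-squares step fit of the raw log2 values around each edge.

    Median smoothing can drag a boundary by a few windows under noise; the
    step fit against the unsmoothed values restores single-window accuracy.
    """
    y = np.log2(np.clip(raw, 2.0 ** -6, None))
    v1 = np.log2(cn / ploidy) if cn > 0 else -6.0
    v0 = 0.0  # baseline
    r = EDGE_SEARCH_WINDOWS

    def fit(edge: int, lo: int, hi: int, left: bool) -> int:
        window = y[lo:hi]
        best_b, best_cost = edge, np.inf
        for b in range(lo, hi + 1):
            if left:
                model = np.where(np.arange(lo, hi) < b, v0, v1)
            else:
                model = np.where(np.arange(lo, hi) < b, v1, v0)
            cost = float(((window - model) ** 2).sum())
            if cost < best_cost:
                best_cost, best_b = cost, b
        return best_b

    left_lo, left_hi = max(0, i - r), min(j - 1, i + r)
    right_lo, right_hi = max(i + 1, j - r), min(len(raw), j + r)
    i2 = fit(i, left_lo, left_hi, left=True)
    j2 = fit(j, right_lo, right_hi, left=False)
    if i2 >= j2:
        return i, j
    return i2, j2


def call_cnv_segments(track: CoverageTrack, ploidy: int) -> list[CNVSegment]:
    """Call gain/loss segments of >= 10 kb from a normalized track.

    Windows are classified to an integer copy number round(value * ploidy)
    (clipped to [0, 2*ploidy]) after a 7-window running-median smoothing;
    candidates are maximal >90%-pure runs of >= 40 windows of one
    non-baseline class, with edges refined by a raw-value step fit.
    Each candidate's raw member values are compared to
    the strain's baseline-classified windows with a two-sided Wilcoxon
    rank-sum test; candidates with p < 0.05 are reported. With fewer than
    100 baseline windows the test is skipped and the segment flagged
    untested.
    """
    if ploidy < 1:
        raise BrewtraceError("ploidy must be >= 1")
    segments: list[CNVSegment] = []
    baseline_values = []
    per_chrom = []
    for chrom in track.windows["chrom"].unique():
        sub = track.windows[track.windows["chrom"] == chrom]
        raw = sub["value"].to_numpy(dtype=float)
        smooth = ndimage.median_filter(raw, size=SMOOTH_WINDOWS, mode="nearest")
        classes = np.clip(np.round(smooth * ploidy), 0, 2 * ploidy).astype(int)
        baseline_values.append(raw[classes == ploidy])
        per_chrom.append((chrom, sub, raw, classes))
    baseline = np.concatenate(baseline_values) if baseline_values else np.array([])

    for chrom, sub, raw, classes in per_chrom:
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for cn in np.unique(classes):
            if cn == ploidy:
                continue
            for i0, j0 in _merge_runs(classes, int(cn)):
                if j0 - i0 < MIN_SEGMENT_WINDOWS:
                    continue
                i, j = _refine_edges(raw, int(i0), int(j0), int(cn), ploidy)
                if j - i < MIN_SEGMENT_WINDOWS:
                    continue
                member = raw[i:j]
                if len(baseline) >= 100:
                    p = float(mannwhitneyu(member, baseline,
                                           alternative="two-sided").pvalue)
                    tested = True
                    if p >= 0.05:
                        continue
                else:
                    p, tested = float("nan"), False
                segments.append(
                    CNVSegment(
                        strain=track.strain,
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        type="gain" if cn > ploidy else "loss",
                        copy_number=int(cn),
                        p_value=p,
                        tested=tested,
                    )
                )
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def cnv_group_frequency(
    segments_by_strain: dict[str, Sequence[CNVSegment]],
    groups: dict[str, str],
    kinship: RelatednessMatrix,
    reference_cnvs: Sequence[CNVSegment],
    n_resamples: int = 20,
    kin_max: float = 0.18,
    overlap_min: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean per-group CNV carrier frequency over kinship-pruned resamples.

    Each resample shuffles the strains, greedily keeps those with pairwise
    kinship < ``kin_max`` to every strain already kept, then force-adds one
    random member for any group left empty. A strain carries a reference
    CNV when one of its same-type segments intersects at least
    ``overlap_min`` of the reference length. Returns reference CNVs (rows,
    labelled chrom:start-end:type) x groups.
    """
    if kinship.kinship is None:
        raise BrewtraceError("kinship matrix required")
    strains = list(groups)
    known = set(kinship.kinship.index)
    absent = [s for s in strains if s not in known]
    if absent:
        raise BrewtraceError(f"strains absent from kinship matrix: {absent}")
    rng = np.random.default_rng(seed)
    kin = kinship.kinship

    carrier = {
        s: [_carries_cnv(segments_by_strain.get(s, ()), ref, overlap_min)
            for ref in reference_cnvs]
        for s in strains
    }
    group_names = sorted(set(groups.values()))
    freq_sum = np.zeros((len(reference_cnvs), len(group_names)))
    for _ in range(n_resamples):
        order = list(rng.permutation(strains))
        kept: list[str] = []
        for s in order:
            vals = [kin.loc[s, t] for t in kept]
            if all(np.isnan(v) or v < kin_max for v in vals):
                kept.append(s)
        for g in group_names:
            if not any(groups[s] == g for s in kept):
                members = [s for s in strains if groups[s] == g]
                kept.append(members[int(rng.integers(len(members)))])
        for gi, g in enumerate(group_names):
            sel = [s for s in kept if groups[s] == g]
            for ri in range(len(reference_cnvs)):
                freq_sum[ri, gi] += sum(carrier[s][ri] for s in sel) / len(sel)
    labels = [f"{r.chrom}:{r.start}-{r.end}:{r.type}" for r in reference_cnvs]
    return pd.DataFrame(freq_sum / n_resamples, index=labels, columns=group_names)


def _carries_cnv(segments: Sequence[CNVSegment], ref: CNVSegment,
                 overlap_min: float) -> bool:
    for seg in segments:
        if seg.type != ref.type or seg.chrom != ref.chrom:
            continue
        overlap = min(seg.end, ref.end) - max(seg.start, ref.start)
        if overlap >= overlap_min * ref.length:
            return True
    return False


def gene_coverage(track: CoverageTrack, genes: IntervalSet) -> pd.Series:
    """Mean normalized coverage over windows intersecting each gene (>= 1 bp);
    genes with no overlapping window are NaN."""
    out = {}
    for gene in genes:
        sub = track.windows[
            (track.windows["chrom"] == gene.chrom)
            & (track.windows["end"] > gene.start)
            & (track.windows["start"] < gene.end)
        ]
        out[gene.label or f"{gene.chrom}:{gene.start}-{gene.end}"] = (
            float(sub["value"].mean()) if len(sub) else float("nan")
        )
    return pd.Series(out)


def cluster_strains(gene_cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of strains (rows) on euclidean
    distance between gene-coverage profiles; returns (linkage, leaf order)."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    if len(gene_cov) < 2:
        raise BrewtraceError("need at least two strains to cluster")
    z = linkage(gene_cov.to_numpy(dtype=float), method="average", metric="euclidean")
    order = [gene_cov.index[i] for i in leaves_list(z)]
    return z, order
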