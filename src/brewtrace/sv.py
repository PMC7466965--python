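"""Structural-variant support filtering and closest-same-class proximity
comparison between strains."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from brewtrace.errors import BrewtraceError
from brewtrace.types import SVCallSet

log = logging.getLogger(__name__)

SUPPORT_FRACTION = 0.15
#: classes with too few calls to compare; excluded from the rank tests
EXCLUDED_CLASSES = ("interspersed_duplication", "inversion")


def filter_sv_support(callset: SVCallSet) -> SVCallSet:
    """Drop calls supported by fewer reads than 15% of the coverage depth
    (strictly fewer: support == ceil is kept)."""
    if callset.depth <= 0:
        log.warning("coverage depth is 0 for %s; keeping all calls", callset.strain)
        return SVCallSet(callset.strain, callset.depth, callset.calls.copy())
    threshold = SUPPORT_FRACTION * callset.depth
    kept = callset.calls[callset.calls["support"] >= threshold].reset_index(drop=True)
    return SVCallSet(callset.strain, callset.depth, kept)


def subsample_reads(
    reads: pd.DataFrame, current_depth: float, target_depth: float, seed: int = 0
) -> pd.DataFrame:
    """Keep each read independently with probability target/current."""
    if current_depth <= 0 or target_depth <= 0:
        raise BrewtraceError("depths must be positive")
    prob = min(1.0, target_depth / current_depth)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < prob if prob < 1.0 else np.ones(len(reads), bool)
    return reads[keep].reset_index(drop=True)


def proximity_distribution(
    a: SVCallSet,
    b: SVCallSet,
    svclass: str,
    chrom_lengths: Optional[dict] = None,
) -> np.ndarray:
    """For every class call in ``a``, distance to the nearest same-class,
    same-chromosome call in ``b``.

    Calls with no same-chromosome mate get the chromosome length as a
    sentinel distance (keeps distribution sizes comparable); this needs
    ``chrom_lengths``, otherwise such calls raise. Asymmetric in (a, b).
    """
    calls_a = a.of_class(svclass)
    calls_b = b.of_class(svclass)
    if len(calls_a) == 0:
        return np.array([])
    out = []
    by_chrom = {c: g["pos"].to_numpy() for c, g in calls_b.groupby("chrom")}
    for chrom, pos in zip(calls_a["chrom"], calls_a["pos"]):
        mates = by_chrom.get(chrom)
        if mates is None or len(mates) == 0:
            if chrom_lengths is None or chrom not in chrom_lengths:
                raise BrewtraceError(
                    f"no same-chromosome mate on {chrom} and no chromosome "
                    "length for the sentinel distance"
                )
            out.append(float(chrom_lengths[chrom]))
        else:
            out.append(float(np.min(np.abs(mates - pos))))
    return np.asarray(out)


@dataclass
class ProximityResult:
    pair: tuple[str, str]
    svclass: str
    distances: np.ndarray
    u_ratio: float = float("nan")
    p_value: float = float("nan")
    fdr_q: float = float("nan")
    right_shifted: bool = False


def proximity_tests(
    pairs: Sequence[ProximityResult],
    reference: np.ndarray,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list[ProximityResult]:
    """One-sided Mann–Whitney U of each distribution vs the reference pair.

    Alternative: the test distribution is stochastically greater than the
    reference (``two_sided`` switches to a two-sided test). p-values are
    Benjamini–Hochberg corrected across all pair x class tests; a
    distribution is flagged right-shifted when its q-value < alpha.
    ``u_ratio`` is U over its null expectation n1*n2/2.
    """
    reference = np.asarray(reference, dtype=float)
    if len(reference) == 0:
        raise BrewtraceError("reference distance distribution is empty")
    results = []
    pvals = []
    for res in pairs:
        if res.svclass in EXCLUDED_CLASSES:
            raise BrewtraceError(
                f"class {res.svclass} is excluded from proximity testing"
            )
        dist = np.asarray(res.distances, dtype=float)
        if len(dist) == 0:
            results.append(
                ProximityResult(res.pair, res.svclass, dist, float("nan"),
                                float("nan"), float("nan"), False)
            )
            pvals.append(None)
            continue
        alternative = "two-sided" if two_sided else "greater"
        test = mannwhitneyu(dist, reference, alternative=alternative,
                            method="asymptotic")
        u_ratio = float(test.statistic) / (len(dist) * len(reference) / 2.0)
        results.append(
            ProximityResult(res.pair, res.svclass, dist, u_ratio,
                            float(test.pvalue), float("nan"), False)
        )
        pvals.append(float(test.pvalue))
    valid = [i for i, p in enumerate(pvals) if p is not None]
    if valid:
        rejected, qvals, _, _ = multipletests(
            [pvals[i] for i in valid], alpha=alpha, method="fdr_bh"
        )
        for k, i in enumerate(valid):
            results[i].fdr_q = float(qvals[k])
            results[i].right_shifted = bool(rejected[k])
    return results
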