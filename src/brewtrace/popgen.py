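"""Genotype filtering, relatedness, diversity statistics and divergence
dating from shared synonymous variants."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from brewtrace.core_io.variants import VariantTable
from brewtrace.errors import BrewtraceError, ConfigurationError

log = logging.getLogger(__name__)

#: per-base per-generation mutation rate used for the molecular clock
MU_PER_GENERATION = 1.67e-10

#: generations-per-year bounds for domesticated/lab yeast
GENERATIONS_PER_YEAR_LOW = 150.0
GENERATIONS_PER_YEAR_HIGH = 2920.0


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterPolicy:
    """Site- and genotype-level hard filters.

    Site filters remove whole records; genotype filters mask individual
    genotypes as MISSING. All comparisons are strict, so a value exactly at
    a threshold passes. ``drop_fs_sor`` waives the FisherStrand and
    StrandOddsRatio filters (they are unstable for single-read evidence).
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    fs_max: float = 60.0
    sor_max: float = 3.0
    readpos_min: float = -8.0
    gq_min: float = 20.0
    dp_min: float = 10.0
    max_missing_fraction: float = 0.10
    drop_fs_sor: bool = False
    require_annotations: bool = True

    def __post_init__(self):
        if not 0 <= self.max_missing_fraction <= 1:
            raise ConfigurationError("max_missing_fraction must lie in [0, 1]")


def _site_fail(vt: VariantTable, key: str, policy: FilterPolicy,
               predicate) -> np.ndarray:
    if key not in vt.site_annotations.columns:
        if policy.require_annotations:
            raise ConfigurationError(
                f"site annotation {key!r} absent and filter not waived"
            )
        log.warning("site annotation %s absent; filter skipped", key)
        return np.zeros(vt.n_sites, dtype=bool)
    vals = vt.site_annotations[key].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        fail = predicate(vals)
    return np.where(np.isnan(vals), False, fail)


def filter_genotypes(vt: VariantTable, policy: FilterPolicy) -> VariantTable:
    """Apply hard filters; returns a new, reduced table.

    Order: indels and multiallelic sites are dropped; sites failing any
    annotation filter are dropped; genotypes with GQ/RGQ below ``gq_min`` or
    DP below ``dp_min`` are masked MISSING; finally sites whose missing
    fraction exceeds ``max_missing_fraction`` are dropped.
    """
    keep = vt.biallelic_snp_mask().copy()
    keep &= ~_site_fail(vt, "QD", policy, lambda v: v < policy.qd_min)
    keep &= ~_site_fail(vt, "MQ", policy, lambda v: v < policy.mq_min)
    keep &= ~_site_fail(vt, "MQRankSum", policy, lambda v: v < policy.mqranksum_min)
    keep &= ~_site_fail(vt, "ReadPosRankSum", policy, lambda v: v < policy.readpos_min)
    if not policy.drop_fs_sor:
        keep &= ~_site_fail(vt, "FS", policy, lambda v: v > policy.fs_max)
        keep &= ~_site_fail(vt, "SOR", policy, lambda v: v > policy.sor_max)
    out = vt.subset_sites(keep)

    # genotype-level masking
    for strain in out.strains:
        ann = out.genotype_annotations.get(strain)
        if ann is None or len(ann.columns) == 0:
            continue
        mask = np.zeros(out.n_sites, dtype=bool)
        quals = [c for c in ("GQ", "RGQ") if c in ann.columns]
        for col in quals:
            vals = ann[col].to_numpy(dtype=float)
            mask |= np.where(np.isnan(vals), False, vals < policy.gq_min)
        if "DP" in ann.columns:
            vals = ann["DP"].to_numpy(dtype=float)
            mask |= np.where(np.isnan(vals), False, vals < policy.dp_min)
        out.genotypes[strain][mask] = -1

    missing = np.zeros(out.n_sites, dtype=float)
    for strain in out.strains:
        missing += out.is_missing(strain)
    frac = missing / max(len(out.strains), 1)
    return out.subset_sites(frac <= policy.max_missing_fraction)


# ---------------------------------------------------------------------------
# relatedness


@dataclass
class RelatednessMatrix:
    strains: list[str]
    ibs: Optional[pd.DataFrame] = None
    kinship: Optional[pd.DataFrame] = None


def _scaled_dosage_matrix(vt: VariantTable) -> np.ndarray:
    """Per-site dosage rescaled to [0, 2]: dosage / (ploidy/2). NaN missing."""
    cols = []
    for s in vt.strains:
        cols.append(vt.dosage(s) / (vt.strain_ploidy[s] / 2.0))
    return np.column_stack(cols)


def ibs_matrix(vt: VariantTable) -> RelatednessMatrix:
    """Identity by state: mean over shared sites of 1 - |x_i - x_j| / 2."""
    x = _scaled_dosage_matrix(vt)
    strains = vt.strains
    n = len(strains)
    ibs = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        valid = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
        if valid.sum() == 0:
            ibs[i, j] = ibs[j, i] = np.nan
            continue
        score = 1.0 - np.abs(x[valid, i] - x[valid, j]) / 2.0
        ibs[i, j] = ibs[j, i] = score.mean()
    return RelatednessMatrix(strains, ibs=pd.DataFrame(ibs, index=strains, columns=strains))


def king_kinship(vt: VariantTable) -> RelatednessMatrix:
    """KING method-of-moments kinship on diploid-collapsed genotypes.

    Polyploid genotypes collapse to hom-ref (dosage 0), het (intermediate)
    or hom-alt (dosage == ploidy). phi = (N_het,het - 2 N_opposite_hom) /
    (N_het(i) + N_het(j)) over shared non-missing sites; the self-kinship is
    0.5 by convention. Pairs with no heterozygous sites are NaN.
    """
    strains = vt.strains
    n = len(strains)
    dosage = {s: vt.dosage(s) for s in strains}
    classes = {}
    for s in strains:
        d = dosage[s]
        p = vt.strain_ploidy[s]
        c = np.full(len(d), -1, dtype=np.int8)  # -1 missing
        c[d == 0] = 0
        c[(d > 0) & (d < p)] = 1
        c[d == p] = 2
        classes[s] = c
    phi = np.full((n, n), 0.5)
    for i, j in combinations(range(n), 2):
        ci, cj = classes[strains[i]], classes[strains[j]]
        valid = (ci >= 0) & (cj >= 0)
        ci, cj = ci[valid], cj[valid]
        n_hh = int(((ci == 1) & (cj == 1)).sum())
        n_opp = int((((ci == 0) & (cj == 2)) | ((ci == 2) & (cj == 0))).sum())
        n_het_i = int((ci == 1).sum())
        n_het_j = int((cj == 1).sum())
        denom = n_het_i + n_het_j
        phi[i, j] = phi[j, i] = (
            (n_hh - 2.0 * n_opp) / denom if denom > 0 else np.nan
        )
    return RelatednessMatrix(
        strains, kinship=pd.DataFrame(phi, index=strains, columns=strains)
    )


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dissimilarity: pd.DataFrame) -> str:
    """Classical Saitou–Nei neighbor joining; returns an unrooted newick.

    Ties in the Q criterion are broken by the lowest index pair. Negative
    branch lengths are kept (not clamped).
    """
    labels = list(dissimilarity.index)
    d = dissimilarity.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1] or len(labels) < 2:
        raise BrewtraceError("dissimilarity matrix must be square with >= 2 taxa")
    nodes = [str(l) for l in labels]
    if len(nodes) == 2:
        h = d[0, 1] / 2.0
        return f"({nodes[0]}:{h:.10g},{nodes[1]}:{h:.10g});"
    active = list(range(len(nodes)))
    newick = {i: nodes[i] for i in active}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        newick[new] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [new]
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    return (
        f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"
    )


# ---------------------------------------------------------------------------
# PCA


def pca(vt: VariantTable, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of mean-centred, sqrt(p(1-p))-scaled dosages.

    Missing dosages are mean-imputed; monomorphic sites are dropped. The
    sign of each component is fixed so its largest-magnitude loading is
    positive. Returns (coordinates, explained variance fractions).
    """
    x = _scaled_dosage_matrix(vt)  # sites x strains in [0, 2]
    col_means = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), col_means, x)
    freq = x.mean(axis=1) / 2.0
    poly = (freq > 0) & (freq < 1)
    x = x[poly]
    freq = freq[poly]
    if x.shape[0] == 0:
        raise BrewtraceError("no polymorphic sites for PCA")
    scaled = (x - 2 * freq[:, None]) / np.sqrt(freq * (1 - freq))[:, None]
    cov = scaled.T @ scaled / scaled.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    k = min(n_components, len(eigvals))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for c in range(k):
        top = np.argmax(np.abs(coords[:, c]))
        if coords[top, c] < 0:
            coords[:, c] = -coords[:, c]
    frame = pd.DataFrame(
        coords, index=vt.strains, columns=[f"PC{c + 1}" for c in range(k)]
    )
    explained = eigvals[:k] / eigvals.sum() if eigvals.sum() > 0 else eigvals[:k]
    return frame, explained


# ---------------------------------------------------------------------------
# diversity / divergence


def _usable_sites(vt: VariantTable, strains: Sequence[str],
                  site_mask: Optional[np.ndarray]) -> np.ndarray:
    mask = vt.biallelic_snp_mask().copy()
    if site_mask is not None:
        mask &= np.asarray(site_mask, dtype=bool)
    for s in strains:
        mask &= ~vt.is_missing(s)
    return mask


def heterozygosity(vt: VariantTable, strain: str,
                   site_mask: Optional[np.ndarray] = None) -> float:
    """Mean pairwise difference among a strain's own alleles, per site."""
    mask = _usable_sites(vt, [strain], site_mask)
    S = int(mask.sum())
    if S == 0:
        raise BrewtraceError("no usable sites")
    p = vt.strain_ploidy[strain]
    if p < 2:
        return 0.0
    d = vt.dosage(strain)[mask]
    pairs = p * (p - 1) / 2.0
    return float(np.sum(d * (p - d) / pairs) / S)


def d_xy(vt: VariantTable, strain_a: str, strain_b: str,
         site_mask: Optional[np.ndarray] = None) -> float:
    """Mean cross-strain allele difference per site."""
    mask = _usable_sites(vt, [strain_a, strain_b], site_mask)
    S = int(mask.sum())
    if S == 0:
        raise BrewtraceError("no usable sites")
    pa, pb = vt.strain_ploidy[strain_a], vt.strain_ploidy[strain_b]
    da, db = vt.dosage(strain_a)[mask], vt.dosage(strain_b)[mask]
    cross_diff = da * (pb - db) + db * (pa - da)
    return float(np.sum(cross_diff / (pa * pb)) / S)


def nucleotide_diversity(vt: VariantTable, strains: Optional[Sequence[str]] = None,
                         site_mask: Optional[np.ndarray] = None) -> float:
    """π over the pooled alleles of a strain group, per site."""
    strains = list(strains) if strains is not None else vt.strains
    mask = _usable_sites(vt, strains, site_mask)
    S = int(mask.sum())
    if S == 0:
        raise BrewtraceError("no usable sites")
    alt = np.zeros(S)
    total = 0
    for s in strains:
        alt += vt.dosage(s)[mask]
        total += vt.strain_ploidy[s]
    pairs = total * (total - 1) / 2.0
    return float(np.sum(alt * (total - alt) / pairs) / S)


def diversity_stats(vt: VariantTable, strains: Optional[Sequence[str]] = None,
                    site_mask: Optional[np.ndarray] = None) -> dict:
    """π for the pooled group, pairwise d_xy and per-strain heterozygosity."""
    strains = list(strains) if strains is not None else vt.strains
    pairwise = pd.DataFrame(0.0, index=strains, columns=strains)
    for a, b in combinations(strains, 2):
        pairwise.loc[a, b] = pairwise.loc[b, a] = d_xy(vt, a, b, site_mask)
    het = pd.Series({s: heterozygosity(vt, s, site_mask) for s in strains})
    return {
        "pi": nucleotide_diversity(vt, strains, site_mask),
        "d_xy": pairwise,
        "heterozygosity": het,
    }


# ---------------------------------------------------------------------------
# divergence dating


@dataclass
class DivergenceEstimate:
    c_focal: int
    c_rel: int
    S: int
    d_pair: float
    f: float
    T_out: float
    T_split: float
    years_range: tuple[int, int] = (0, 0)


def synonymous_mask(vt: VariantTable) -> np.ndarray:
    if "SYN" not in vt.site_annotations.columns:
        raise ConfigurationError("variant table carries no SYN annotation")
    return vt.site_annotations["SYN"].to_numpy(dtype=float) > 0


def branch_fraction(
    vt: VariantTable,
    focal: str,
    relative: str,
    site_mask: Optional[np.ndarray] = None,
    mu: float = MU_PER_GENERATION,
) -> DivergenceEstimate:
    """Date the focal/relative split from private synonymous variants.

    Counts sites where one strain carries an alternate allele (>= 1 copy)
    while the other matches the reference; the averaged count per
    no-missing-data synonymous site is the divergence accumulated since the
    split, and dividing by half the pairwise focal-reference synonymous
    divergence gives the fraction f of the focal branch it represents.
    T_out comes from the molecular clock and T_split = f * T_out.
    """
    if site_mask is None:
        site_mask = synonymous_mask(vt)
    mask = _usable_sites(vt, [focal, relative], site_mask)
    S = int(mask.sum())
    if S == 0:
        raise BrewtraceError("no synonymous sites with complete data")
    carries_f = vt.carries(focal)[mask]
    carries_r = vt.carries(relative)[mask]
    c_focal = int((carries_f & ~carries_r).sum())
    c_rel = int((carries_r & ~carries_f).sum())
    p = vt.strain_ploidy[focal]
    d_pair = float(np.sum(vt.dosage(focal)[mask] / p) / S)
    per_site = 0.5 * (c_focal + c_rel) / S
    f = min(1.0, max(0.0, per_site / (d_pair / 2.0))) if d_pair > 0 else 0.0
    T_out = clock_generations(d_pair, mu)
    T_split = f * T_out
    return DivergenceEstimate(
        c_focal=c_focal,
        c_rel=c_rel,
        S=S,
        d_pair=d_pair,
        f=f,
        T_out=T_out,
        T_split=T_split,
        years_range=generations_to_years(T_split),
    )


def clock_generations(d_pair: float, mu: float = MU_PER_GENERATION) -> float:
    """Generations to the common ancestor: T = d / (2 mu)."""
    if mu <= 0:
        raise BrewtraceError("mutation rate must be positive")
    if d_pair < 0:
        raise BrewtraceError("divergence cannot be negative")
    return d_pair / (2.0 * mu)


def generations_to_years(
    generations: float,
    per_year_low: float = GENERATIONS_PER_YEAR_LOW,
    per_year_high: float = GENERATIONS_PER_YEAR_HIGH,
) -> tuple[int, int]:
    """(years at the fast rate, floored; years at the slow rate, rounded)."""
    if generations < 0:
        raise BrewtraceError("generations cannot be negative")
    return (
        int(math.floor(generations / per_year_high)),
        int(round(generations / per_year_low)),
    )
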