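"""Simulators for every input class the analysis stages consume.

Each generator is bit-reproducible under a fixed seed. Long reads are
error-free with exact truth mappings: the read simulator's purpose is to
exercise binning/counting logic, not to model sequencing chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from brewtrace.core_io.genome import (
    CoordinateMap,
    Feature,
    GenomeModel,
    Interval,
    MapBlock,
)
from brewtrace.core_io.variants import VariantTable
from brewtrace.errors import BrewtraceError
from brewtrace.types import (
    CoverageTrack,
    FluorescenceSample,
    GrowthCurve,
    SplitReadSet,
    SVCallSet,
)

# ---------------------------------------------------------------------------
# configs


@dataclass
class PopSimConfig:
    """Clock-like divergence of a focal/relative pair against an outgroup
    reference, with shared ancestral heterozygosity."""

    n_syn_sites: int = 50_000
    n_nonsyn_sites: int = 0
    mu: float = 1e-8
    T_outgroup: float = 1e6
    T_split: float = 1e5
    theta_anc: float = 0.0
    ploidy: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.T_split <= self.T_outgroup:
            raise BrewtraceError("need 0 <= T_split <= T_outgroup")
        if self.ploidy < 1:
            raise BrewtraceError("ploidy must be >= 1")


@dataclass
class CoverageSimConfig:
    chrom_lengths: dict = field(default_factory=lambda: {"chrI": 200_000})
    baseline_ploidy: int = 4
    events: list = field(default_factory=list)  # (chrom, start, end, copy_number)
    slope: float = 0.0
    noise_sd: float = 0.0
    window: int = 250
    seed: int = 0

    def __post_init__(self):
        if self.window <= 0:
            raise BrewtraceError("window must be positive")
        for chrom, start, end, _cn in self.events:
            if chrom not in self.chrom_lengths:
                raise BrewtraceError(f"event on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise BrewtraceError(f"event {chrom}:{start}-{end} outside chromosome")


@dataclass
class ReadSimConfig:
    depth: float = 60.0
    length_mean: float = 3000.0
    length_sd: float = 2300.0
    min_len: int = 8000
    max_len: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise BrewtraceError("min_len must be <= max_len")
        if self.depth <= 0:
            raise BrewtraceError("depth must be positive")


@dataclass
class TruthRecord:
    """Ground truth written alongside a simulated population."""

    T_outgroup: float
    T_split: float
    f_true: float
    n_focal_private_syn: int
    n_relative_private_syn: int
    n_shared_syn: int
    n_anc_het_syn: int
    n_focal_private: int
    n_relative_private: int
    n_shared: int
    n_anc_het: int


# ---------------------------------------------------------------------------
# population


def simulate_population(cfg: PopSimConfig) -> tuple[VariantTable, TruthRecord]:
    """Place infinite-sites mutations on the three informative branches.

    Categories per site class (synonymous / nonsynonymous):
      * focal-private: Poisson(mu * T_split * n), alt fixed in focal only;
      * relative-private: same mean, alt fixed in relative only;
      * shared: Poisson(mu * (2*T_outgroup - T_split) * n), alt fixed in both
        (internal branch plus the reference's own lineage are
        indistinguishable against the reference and are pooled);
      * ancestral het: Poisson(theta_anc * n), same intermediate dosage in
        both strains.

    The returned table contains *all* sites, monomorphic ones included, so
    that downstream denominators (synonymous sites with no missing data)
    are well defined.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_syn_sites + cfg.n_nonsyn_sites
    if n_total == 0:
        raise BrewtraceError("no sites configured")
    p = cfg.ploidy

    syn = np.zeros(n_total, dtype=bool)
    syn[rng.choice(n_total, size=cfg.n_syn_sites, replace=False)] = True

    geno = {
        "focal": np.zeros((n_total, p), dtype=np.int16),
        "relative": np.zeros((n_total, p), dtype=np.int16),
    }
    counts = {}
    means = {
        "focal_private": cfg.mu * cfg.T_split,
        "relative_private": cfg.mu * cfg.T_split,
        "shared": cfg.mu * (2 * cfg.T_outgroup - cfg.T_split),
        "anc_het": cfg.theta_anc,
    }
    for is_syn, n_class in ((True, cfg.n_syn_sites), (False, cfg.n_nonsyn_sites)):
        if n_class == 0:
            for cat in means:
                counts[(cat, is_syn)] = 0
            continue
        ks = {cat: int(rng.poisson(m * n_class)) for cat, m in means.items()}
        k_total = sum(ks.values())
        if k_total > n_class / 10:
            raise BrewtraceError(
                f"expected mutation count {k_total} exceeds n_sites/10 "
                f"({n_class / 10:.0f}): infinite-sites regime violated"
            )
        class_positions = np.flatnonzero(syn == is_syn)
        chosen = rng.choice(class_positions, size=k_total, replace=False)
        idx = 0
        for cat, k in ks.items():
            sites = chosen[idx : idx + k]
            idx += k
            counts[(cat, is_syn)] = k
            if cat == "focal_private":
                geno["focal"][sites] = 1
            elif cat == "relative_private":
                geno["relative"][sites] = 1
            elif cat == "shared":
                geno["focal"][sites] = 1
                geno["relative"][sites] = 1
            else:  # ancestral heterozygosity, intermediate dosage in both
                dosages = rng.integers(1, p, size=k) if p > 1 else np.ones(k, int)
                for site, d in zip(sites, dosages):
                    geno["focal"][site, :d] = 1
                    geno["relative"][site, :d] = 1

    variant = (geno["focal"] >= 1).any(axis=1) | (geno["relative"] >= 1).any(axis=1)
    sites = pd.DataFrame(
        {
            "chrom": np.repeat("chrS", n_total),
            "pos": np.arange(n_total),
            "ref": np.repeat("A", n_total),
            "alt": np.where(variant, "T", "."),
            "is_indel": False,
            "is_multiallelic": False,
        }
    )
    annotations = pd.DataFrame({"SYN": syn.astype(float)})
    vt = VariantTable(
        sites,
        geno,
        {"focal": p, "relative": p},
        annotations,
    )
    truth = TruthRecord(
        T_outgroup=cfg.T_outgroup,
        T_split=cfg.T_split,
        f_true=cfg.T_split / cfg.T_outgroup if cfg.T_outgroup else 0.0,
        n_focal_private_syn=counts[("focal_private", True)],
        n_relative_private_syn=counts[("relative_private", True)],
        n_shared_syn=counts[("shared", True)],
        n_anc_het_syn=counts[("anc_het", True)],
        n_focal_private=counts[("focal_private", True)] + counts[("focal_private", False)],
        n_relative_private=counts[("relative_private", True)] + counts[("relative_private", False)],
        n_shared=counts[("shared", True)] + counts[("shared", False)],
        n_anc_het=counts[("anc_het", True)] + counts[("anc_het", False)],
    )
    return vt, truth


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(cfg: CoverageSimConfig, strain: str = "sim") -> CoverageTrack:
    """Window value = (copy_number/baseline) * 2^(slope*x) * 2^eps with
    x the normalized distance from the chromosome midpoint."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for chrom, length in cfg.chrom_lengths.items():
        n_win = length // cfg.window
        if n_win == 0:
            continue
        starts = np.arange(n_win) * cfg.window
        ends = starts + cfg.window
        centers = (starts + ends) / 2
        mid = length / 2
        x = np.abs(centers - mid) / mid
        cn = np.full(n_win, float(cfg.baseline_ploidy))
        for ev_chrom, ev_start, ev_end, ev_cn in cfg.events:
            if ev_chrom == chrom:
                inside = (starts >= ev_start) & (ends <= ev_end)
                cn[inside] = ev_cn
        eps = rng.normal(0.0, cfg.noise_sd, size=n_win) if cfg.noise_sd > 0 else 0.0
        value = (cn / cfg.baseline_ploidy) * np.exp2(cfg.slope * x) * np.exp2(eps)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": value})
        )
    if not frames:
        raise BrewtraceError("no chromosome long enough for a single window")
    return CoverageTrack(
        strain, pd.concat(frames, ignore_index=True), cfg.window, dict(cfg.chrom_lengths)
    )


# ---------------------------------------------------------------------------
# rearrangement + long reads


def simulate_translocation(
    genome: GenomeModel,
    bpA: Interval,
    bpB: Interval,
    cut: float = 0.5,
) -> tuple[GenomeModel, CoordinateMap]:
    """Reciprocal exchange at the internal cut point of two same-strand
    breakpoint intervals on different chromosomes.

    Returns the rearranged genome and the map from rearranged coordinates
    back to the input genome. Total genome length is conserved; features are
    remapped, with junction-spanning features split into ``_5p``/``_3p``
    parts.
    """
    if bpA.chrom == bpB.chrom:
        raise BrewtraceError("translocation within one chromosome is unsupported")
    if not 0.0 <= cut <= 1.0:
        raise BrewtraceError("cut must lie in [0, 1]")
    cutA = bpA.start + int(round(cut * (bpA.end - bpA.start)))
    cutB = bpB.start + int(round(cut * (bpB.end - bpB.start)))
    lenA, lenB = genome.lengths[bpA.chrom], genome.lengths[bpB.chrom]

    chromosomes: list[tuple[str, object]] = []
    for name in genome.chrom_names:
        if name == bpA.chrom:
            if genome.sequences[name] is not None:
                seqA = genome.sequence(bpA.chrom)
                seqB = genome.sequence(bpB.chrom)
                chromosomes.append((name, seqA[:cutA] + seqB[cutB:]))
            else:
                chromosomes.append((name, cutA + (lenB - cutB)))
        elif name == bpB.chrom:
            if genome.sequences[name] is not None:
                seqA = genome.sequence(bpA.chrom)
                seqB = genome.sequence(bpB.chrom)
                chromosomes.append((name, seqB[:cutB] + seqA[cutA:]))
            else:
                chromosomes.append((name, cutB + (lenA - cutA)))
        else:
            payload = genome.sequences[name]
            chromosomes.append((name, payload if payload is not None else genome.lengths[name]))

    cuts = {bpA.chrom: (cutA, bpB.chrom, cutB), bpB.chrom: (cutB, bpA.chrom, cutA)}
    features = []
    for f in genome.features:
        if f.chrom not in cuts:
            features.append(f)
            continue
        cut_pos, other, other_cut = cuts[f.chrom]
        if f.end <= cut_pos:
            features.append(f)
        elif f.start >= cut_pos:
            off = f.start - cut_pos
            features.append(
                Feature(other, other_cut + off, other_cut + off + f.length,
                        f.strand, f.kind, f.id)
            )
        else:
            features.append(Feature(f.chrom, f.start, cut_pos, f.strand, f.kind,
                                    f.id + "_5p" if f.id else ""))
            features.append(Feature(other, other_cut, other_cut + (f.end - cut_pos),
                                    f.strand, f.kind, f.id + "_3p" if f.id else ""))

    derived = GenomeModel(chromosomes, features)
    blocks = []
    for name in genome.chrom_names:
        if name == bpA.chrom:
            blocks.append(MapBlock(name, 0, cutA, bpA.chrom, 0))
            blocks.append(MapBlock(name, cutA, cutA + (lenB - cutB), bpB.chrom, cutB))
        elif name == bpB.chrom:
            blocks.append(MapBlock(name, 0, cutB, bpB.chrom, 0))
            blocks.append(MapBlock(name, cutB, cutB + (lenA - cutA), bpA.chrom, cutA))
        else:
            blocks.append(MapBlock(name, 0, genome.lengths[name], name, 0))
    return derived, CoordinateMap(blocks)


def apply_translocations(
    genome: GenomeModel,
    pairs: Iterable[tuple[Interval, Interval]],
    cut: float = 0.5,
) -> tuple[GenomeModel, CoordinateMap]:
    """Apply several reciprocal translocations, composing the truth maps."""
    current = genome
    total = CoordinateMap.identity(genome)
    for bpA, bpB in pairs:
        current, step = simulate_translocation(current, bpA, bpB, cut)
        total = step.compose(total)
    return current, total


def simulate_long_reads(
    genome: GenomeModel,
    truth_map: CoordinateMap,
    cfg: ReadSimConfig,
) -> tuple[pd.DataFrame, SplitReadSet]:
    """Error-free long reads with exact reference-space split mappings.

    Read starts are uniform; lengths are Normal(length_mean, length_sd)
    truncated to [min_len, max_len] by rejection. Reads overhanging a
    chromosome end are clipped. Each read's alignment segments are computed
    exactly from the truth map: the longest segment is flagged primary, the
    rest supplementary; no secondary records are emitted here.
    """
    if genome.total_length == 0:
        raise BrewtraceError("empty genome")
    rng = np.random.default_rng(cfg.seed)
    target = cfg.depth * genome.total_length
    names = genome.chrom_names
    lengths = np.array([genome.lengths[n] for n in names], dtype=float)
    weights = lengths / lengths.sum()

    def draw_lengths(k: int) -> np.ndarray:
        out = np.empty(0)
        while len(out) < k:
            cand = rng.normal(cfg.length_mean, cfg.length_sd, size=4 * k)
            cand = cand[(cand >= cfg.min_len) & (cand <= cfg.max_len)]
            out = np.concatenate([out, cand])
        return out[:k].astype(int)

    reads, records = [], []
    total_bases, read_no = 0, 0
    batch = max(64, int(target / max(cfg.length_mean, cfg.min_len)) // 4 + 1)
    while total_bases < target:
        chrom_idx = rng.choice(len(names), size=batch, p=weights)
        lens = draw_lengths(batch)
        for ci, L in zip(chrom_idx, lens):
            if total_bases >= target:
                break
            chrom = names[ci]
            clen = genome.lengths[chrom]
            start = int(rng.integers(0, clen))
            end = min(start + int(L), clen)
            if end - start < 50:  # degenerate clip at the very end
                continue
            rid = f"read{read_no:07d}"
            read_no += 1
            rlen = end - start
            total_bases += rlen
            reads.append((rid, chrom, start, end, rlen))
            segments = truth_map.map_interval(chrom, start, end)
            seg_rows = []
            for src_lo, src_hi, dst_chrom, dst_s, dst_e in segments:
                seg_rows.append(
                    (rid, rlen, src_lo - start, src_hi - start,
                     dst_chrom, dst_s, dst_e, "+", "supplementary")
                )
            if seg_rows:
                longest = max(range(len(seg_rows)), key=lambda i: seg_rows[i][3] - seg_rows[i][2])
                seg_rows[longest] = seg_rows[longest][:8] + ("primary",)
            records.extend(seg_rows)

    read_df = pd.DataFrame(reads, columns=["read_id", "chrom", "start", "end", "length"])
    rec_df = pd.DataFrame(
        records,
        columns=["read_id", "read_len", "read_start", "read_end",
                 "chrom", "start", "end", "strand", "flag"],
    )
    return read_df, SplitReadSet(rec_df, genome.total_length, int(total_bases))


def demote_repeat_segments(reads: SplitReadSet, reference: GenomeModel) -> SplitReadSet:
    """Emulate repeat-induced mapping ambiguity: flag as secondary any
    segment lying entirely within a repeat element that has a same-strand
    homologous copy elsewhere (its alignment would be non-unique)."""
    repeats = [f for f in reference.features_of_kind("repeat_element")]
    by_family: dict[tuple[str, str], int] = {}
    for f in repeats:
        by_family[(f.id.split("#")[0], f.strand)] = by_family.get(
            (f.id.split("#")[0], f.strand), 0
        ) + 1
    ambiguous = [
        f for f in repeats if by_family[(f.id.split("#")[0], f.strand)] >= 2
    ]
    if not ambiguous:
        return reads
    rec = reads.records.copy()
    chrom = rec["chrom"].to_numpy()
    start = rec["start"].to_numpy()
    end = rec["end"].to_numpy()
    inside = np.zeros(len(rec), dtype=bool)
    for f in ambiguous:
        inside |= (chrom == f.chrom) & (start >= f.start) & (end <= f.end)
    rec.loc[inside, "flag"] = "secondary"
    return SplitReadSet(rec, reads.genome_length, reads.total_read_bases)


# ---------------------------------------------------------------------------
# growth, cytometry, SV call sets


def simulate_growth_curve(
    r: float,
    K: float = 1.2,
    od0: float = 0.1,
    dt: float = 0.25,
    horizon: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    strain: str = "sim",
    condition: str = "",
) -> GrowthCurve:
    """Logistic OD(t) = K / (1 + ((K-od0)/od0) e^{-rt}) plus Gaussian noise."""
    if od0 <= 0 or K <= 0:
        raise BrewtraceError("K and od0 must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon + dt / 2, dt)
    od = K / (1.0 + ((K - od0) / od0) * np.exp(-r * times))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=len(times))
    return GrowthCurve(times, od, strain=strain, condition=condition)


def simulate_cytometry(
    g1_mean: float,
    cv: float = 0.03,
    g2_fraction: float = 0.4,
    n_cells: int = 5000,
    seed: int = 0,
    strain: str = "sim",
) -> FluorescenceSample:
    """Two-component Normal mixture at g1_mean and 2*g1_mean."""
    if not 0 <= g2_fraction <= 1:
        raise BrewtraceError("g2_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_g2 = int(rng.binomial(n_cells, g2_fraction))
    g1 = rng.normal(g1_mean, cv * g1_mean, size=n_cells - n_g2)
    g2 = rng.normal(2 * g1_mean, cv * 2 * g1_mean, size=n_g2)
    values = np.clip(np.concatenate([g1, g2]), 1e-9, None)
    rng.shuffle(values)
    return FluorescenceSample(values, strain=strain)


def simulate_sv_callsets(
    n_calls: int,
    shared_fraction: float,
    jitter_sd: float,
    chrom_lengths: dict,
    classes: Sequence[str] = ("deletion", "insertion", "tandem_duplication"),
    seed: int = 0,
    depth: float = 60.0,
) -> tuple[SVCallSet, SVCallSet]:
    """Pair of call sets sharing ``shared_fraction`` of calls.

    Shared calls appear in both sets, the copy in set B perturbed by
    Normal(0, jitter_sd); the remainder is uniform and independent per set.
    """
    if not 0 <= shared_fraction <= 1:
        raise BrewtraceError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights = lengths / lengths.sum()
    n_shared = int(round(shared_fraction * n_calls))

    def uniform_calls(k: int) -> pd.DataFrame:
        ci = rng.choice(len(names), size=k, p=weights)
        pos = (rng.random(k) * lengths[ci]).astype(int)
        return pd.DataFrame(
            {
                "chrom": [names[i] for i in ci],
                "pos": pos,
                "svclass": rng.choice(classes, size=k),
                "support": np.maximum(1, rng.poisson(depth / 2, size=k)),
            }
        )

    shared = uniform_calls(n_shared)
    jittered = shared.copy()
    if jitter_sd > 0 and n_shared:
        shift = rng.normal(0.0, jitter_sd, size=n_shared)
        lims = np.array([chrom_lengths[c] for c in jittered["chrom"]])
        jittered["pos"] = np.clip(
            jittered["pos"].to_numpy() + np.round(shift).astype(int), 0, lims - 1
        )
    a = pd.concat([shared, uniform_calls(n_calls - n_shared)], ignore_index=True)
    b = pd.concat([jittered, uniform_calls(n_calls - n_shared)], ignore_index=True)
    return (
        SVCallSet("simA", depth, a),
        SVCallSet("simB", depth, b),
    )
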