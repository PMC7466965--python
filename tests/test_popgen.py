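"""popgen: filters, relatedness, NJ vs minimum-evolution oracle, PCA,
diversity statistics and the divergence-dating estimator."""

from __future__ import annotations

from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
import pytest

from brewtrace.errors import BrewtraceError, ConfigurationError
from brewtrace.popgen import (
    FilterPolicy,
    branch_fraction,
    clock_generations,
    d_xy,
    diversity_stats,
    filter_genotypes,
    generations_to_years,
    heterozygosity,
    ibs_matrix,
    king_kinship,
    nj_tree,
    nucleotide_diversity,
    pca,
    synonymous_mask,
)
from brewtrace.synthetic_data import PopSimConfig, simulate_population

from conftest import make_variant_table

MU = 1.67e-10


# ---------------------------------------------------------------------------
# filtering


def annotated_table(qd=None, dp=None, n_strains=2, n_sites=3):
    genos = {f"s{i}": [(0, 1)] * n_sites for i in range(n_strains)}
    ann = pd.DataFrame(
        {
            "QD": qd if qd is not None else [10.0] * n_sites,
            "MQ": [50.0] * n_sites,
            "MQRankSum": [0.0] * n_sites,
            "ReadPosRankSum": [0.0] * n_sites,
            "FS": [1.0] * n_sites,
            "SOR": [1.0] * n_sites,
        }
    )
    gt_ann = {
        s: pd.DataFrame(
            {
                "GQ": [99.0] * n_sites,
                "RGQ": [99.0] * n_sites,
                "DP": dp.get(s, [30.0] * n_sites) if dp else [30.0] * n_sites,
            }
        )
        for s in genos
    }
    return make_variant_table(genos, ploidy=2, site_annotations=ann,
                              genotype_annotations=gt_ann)


class TestFilterGenotypes:
    def test_low_qd_removed(self):
        vt = annotated_table(qd=[1.5, 2.0, 10.0])
        out = filter_genotypes(vt, FilterPolicy())
        # QD < 2 removed; QD == 2 passes (strict comparison)
        assert out.n_sites == 2

    def test_low_dp_masked(self):
        vt = annotated_table(dp={"s0": [9.0, 30.0, 30.0]})
        out = filter_genotypes(vt, FilterPolicy(max_missing_fraction=1.0))
        assert out.is_missing("s0").tolist() == [True, False, False]
        assert not out.is_missing("s1").any()

    def test_missing_fraction_rule(self):
        genos = {f"s{i}": [(0, 1)] for i in range(10)}
        genos["s0"] = [None]
        genos["s1"] = [None]
        vt = make_variant_table(genos, ploidy=2)
        out = filter_genotypes(
            vt, FilterPolicy(require_annotations=False)
        )
        assert out.n_sites == 0  # 2/10 = 0.2 > 0.10

    def test_absent_annotation_errors(self):
        vt = make_variant_table({"s": [(0, 1)]}, ploidy=2)
        with pytest.raises(ConfigurationError):
            filter_genotypes(vt, FilterPolicy())

    def test_fs_sor_waived(self):
        vt = annotated_table()
        vt.site_annotations.drop(columns=["FS", "SOR"], inplace=True)
        out = filter_genotypes(vt, FilterPolicy(drop_fs_sor=True))
        assert out.n_sites == 3

    def test_indels_multiallelics_dropped(self):
        vt = annotated_table(n_sites=3)
        vt.sites.loc[0, "is_indel"] = True
        vt.sites.loc[1, "is_multiallelic"] = True
        out = filter_genotypes(vt, FilterPolicy())
        assert out.n_sites == 1


# ---------------------------------------------------------------------------
# relatedness


class TestIbsMatrix:
    def test_identical_strains(self):
        vt = make_variant_table(
            {"a": [(0, 0, 1, 1), (1, 1, 1, 1)], "b": [(0, 0, 1, 1), (1, 1, 1, 1)]}
        )
        m = ibs_matrix(vt)
        assert m.ibs.loc["a", "b"] == 1.0

    def test_opposite_homozygotes(self):
        vt = make_variant_table({"a": [(0, 0), (0, 0)], "b": [(1, 1), (1, 1)]}, ploidy=2)
        assert ibs_matrix(vt).ibs.loc["a", "b"] == 0.0

    def test_diploid_half_step(self):
        vt = make_variant_table({"a": [(0, 1)], "b": [(1, 1)]}, ploidy=2)
        assert ibs_matrix(vt).ibs.loc["a", "b"] == 0.5

    def test_diagonal_exactly_one(self):
        vt = make_variant_table({"a": [(0, 1)], "b": [(1, 1)]}, ploidy=2)
        assert (np.diag(ibs_matrix(vt).ibs.to_numpy()) == 1.0).all()


class TestKingKinship:
    def test_self_half(self):
        vt = make_variant_table({"a": [(0, 1), (0, 0)]}, ploidy=2)
        assert king_kinship(vt).kinship.loc["a", "a"] == 0.5

    def test_formula_case(self):
        # N_het,het = 4, N_opp = 1, N_het(a) = N_het(b) = 6
        a = [(0, 1)] * 4 + [(0, 0)] + [(0, 1)] * 2 + [(0, 0)] * 2
        b = [(0, 1)] * 4 + [(1, 1)] + [(0, 0)] * 2 + [(0, 1)] * 2
        vt = make_variant_table({"a": a, "b": b}, ploidy=2)
        assert king_kinship(vt).kinship.loc["a", "b"] == pytest.approx((4 - 2) / 12)

    def test_inbred_lines_negative(self):
        vt = make_variant_table(
            {"a": [(0, 0), (1, 1), (0, 1)], "b": [(1, 1), (0, 0), (0, 1)]}, ploidy=2
        )
        assert king_kinship(vt).kinship.loc["a", "b"] < 0

    def test_no_het_pair_nan(self):
        vt = make_variant_table({"a": [(0, 0)], "b": [(1, 1)]}, ploidy=2)
        assert np.isnan(king_kinship(vt).kinship.loc["a", "b"])


# ---------------------------------------------------------------------------
# neighbor joining with an exhaustive minimum-evolution oracle


def tree_distances(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ns = {t.label: t for t in tree.taxon_namespace}
    return {
        (a, b): pdm.patristic_distance(ns[a], ns[b]) for a, b in combinations(taxa, 2)
    }


def me_oracle(d: pd.DataFrame) -> set[frozenset]:
    """Exhaustive minimum-evolution over unrooted topologies (<= 5 taxa):
    least-squares branch lengths per topology, minimal total length wins.
    Returns the non-trivial splits of the best topology."""
    taxa = list(d.index)
    n = len(taxa)
    assert n in (4, 5)

    def topologies():
        if n == 4:
            a, b, c, e = taxa
            yield [frozenset({a, b})]
            yield [frozenset({a, c})]
            yield [frozenset({a, e})]
        else:
            # all 15 unrooted 5-taxon topologies = two disjoint cherries
            from itertools import combinations as comb

            splits2 = [frozenset(s) for s in comb(taxa, 2)]
            for s1, s2 in comb(splits2, 2):
                if not s1 & s2:
                    yield [s1, s2]

    def total_length(splits):
        # branch-length design matrix: edges = terminal (n) + internal splits
        pairs = list(combinations(taxa, 2))
        edges = taxa + splits
        A = np.zeros((len(pairs), len(edges)))
        for r, (x, y) in enumerate(pairs):
            A[r, taxa.index(x)] = 1
            A[r, taxa.index(y)] = 1
            for c, s in enumerate(splits):
                if (x in s) != (y in s):
                    A[r, n + c] = 1
        y = np.array([d.loc[x, z] for x, z in pairs])
        lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(np.abs(A @ lengths - y).sum())
        return float(lengths.sum()), resid

    best, best_len, best_resid = None, np.inf, np.inf
    for splits in topologies():
        tl, resid = total_length(splits)
        if (resid, tl) < (best_resid, best_len):
            best, best_len, best_resid = splits, tl, resid
    return {canonical_split(s, taxa) for s in best}


def canonical_split(side, taxa) -> frozenset:
    """A bipartition equals its complement; keep the side without the
    alphabetically first taxon."""
    side = frozenset(side)
    if sorted(taxa)[0] in side:
        side = frozenset(taxa) - side
    return side


def newick_splits(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    out = set()
    for bp in tree.bipartition_encoding:
        side = {t.label for t in tree.taxon_namespace
                if bp.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)}
        if 1 < len(side) < len(taxa) - 1:
            out.add(canonical_split(side, taxa))
    return out


def additive_matrix():
    # tree ((A:1,B:2):1,C:3,D:4) with internal edge 1
    taxa = ["A", "B", "C", "D"]
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    paths = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    for (x, y), v in paths.items():
        d.loc[x, y] = d.loc[y, x] = v
    return d


class TestNjTree:
    def test_recovers_additive_topology(self):
        d = additive_matrix()
        newick = nj_tree(d)
        assert newick_splits(newick, list(d.index)) == me_oracle(d)
        # and the recovered branch lengths reproduce the path distances
        got = tree_distances(newick, list(d.index))
        for (x, y), v in got.items():
            assert v == pytest.approx(d.loc[x, y])

    def test_three_taxa_closed_form(self):
        taxa = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 4, 6], [4, 0, 8], [6, 8, 0]], index=taxa, columns=taxa, dtype=float
        )
        newick = nj_tree(d)
        got = tree_distances(newick, taxa)
        assert got[("A", "B")] == pytest.approx(4)
        assert got[("A", "C")] == pytest.approx(6)
        assert got[("B", "C")] == pytest.approx(8)

    def test_permutation_invariant_topology(self):
        d = additive_matrix()
        perm = ["C", "A", "D", "B"]
        newick1 = nj_tree(d)
        newick2 = nj_tree(d.loc[perm, perm])
        taxa = list(d.index)
        assert newick_splits(newick1, taxa) == newick_splits(newick2, taxa)

    def test_five_taxa_vs_oracle(self, rng):
        # additive distances from a random 5-taxon tree
        taxa = ["A", "B", "C", "D", "E"]
        # tree: ((A,B),(C,D),E) with random positive branch lengths
        bl = dict(zip(["A", "B", "C", "D", "E", "ab", "cd"],
                      rng.uniform(0.5, 3.0, size=7)))
        d = pd.DataFrame(0.0, index=taxa, columns=taxa)

        def path(x, y):
            up = {"A": ["A", "ab"], "B": ["B", "ab"], "C": ["C", "cd"],
                  "D": ["D", "cd"], "E": ["E"]}
            ex, ey = up[x], up[y]
            shared = set(ex) & set(ey)
            return sum(bl[e] for e in set(ex) ^ set(ey) | (set() if shared else set()))

        for x, y in combinations(taxa, 2):
            d.loc[x, y] = d.loc[y, x] = path(x, y)
        newick = nj_tree(d)
        expected = {canonical_split({"A", "B"}, taxa), canonical_split({"C", "D"}, taxa)}
        assert newick_splits(newick, taxa) == expected == me_oracle(d)


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_duplicated_strain_identical(self, rng):
        genos = {
            "a": [tuple(rng.integers(0, 2, 2)) for _ in range(50)],
        }
        genos["a_dup"] = list(genos["a"])
        genos["b"] = [tuple(rng.integers(0, 2, 2)) for _ in range(50)]
        vt = make_variant_table(genos, ploidy=2)
        coords, _ = pca(vt, 2)
        assert np.allclose(coords.loc["a"], coords.loc["a_dup"])

    def test_two_populations_separate(self, rng):
        from sklearn.metrics import silhouette_score

        n_sites = 200
        genos = {}
        for i in range(6):
            genos[f"p1_{i}"] = [
                (1, 1) if rng.random() < 0.9 else (0, 0) for _ in range(n_sites)
            ]
        for i in range(6):
            genos[f"p2_{i}"] = [
                (0, 0) if rng.random() < 0.9 else (1, 1) for _ in range(n_sites)
            ]
        vt = make_variant_table(genos, ploidy=2)
        coords, _ = pca(vt, 2)
        labels = [s.split("_")[0] for s in coords.index]
        assert silhouette_score(coords.to_numpy(), labels) > 0.8

    def test_explained_variance_bounded(self, rng):
        genos = {
            f"s{i}": [tuple(rng.integers(0, 2, 2)) for _ in range(40)] for i in range(5)
        }
        vt = make_variant_table(genos, ploidy=2)
        _, explained = pca(vt, 4)
        assert explained.sum() <= 1.0 + 1e-9
        assert (explained >= 0).all()


# ---------------------------------------------------------------------------
# diversity


class TestDiversityStats:
    def test_monomorphic_zero(self):
        vt = make_variant_table({"a": [(0, 0)] * 5, "b": [(0, 0)] * 5}, ploidy=2)
        stats = diversity_stats(vt)
        assert stats["pi"] == 0.0
        assert (stats["heterozygosity"] == 0).all()
        assert (stats["d_xy"].to_numpy() == 0).all()

    def test_tetraploid_heterozygosity(self):
        # one {2 ref, 2 alt} site among 100 -> (4/6)/100
        genos = {"a": [(0, 0, 1, 1)] + [(0, 0, 0, 0)] * 99}
        vt = make_variant_table(genos, ploidy=4)
        assert heterozygosity(vt, "a") == pytest.approx((4 / 6) / 100)

    def test_identical_strains_dxy_vs_het(self):
        # identical allele pools: d_xy (all p*p cross pairs, self-pairings
        # included) equals het (C(p,2) within pairs) scaled by (p-1)/p
        genos = {"a": [(0, 0, 1, 1), (0, 1, 1, 1)] + [(0, 0, 0, 0)] * 48}
        genos["b"] = list(genos["a"])
        vt = make_variant_table(genos, ploidy=4)
        p = 4
        assert d_xy(vt, "a", "b") == pytest.approx(
            heterozygosity(vt, "a") * (p - 1) / p
        )

    def test_pooled_pi(self):
        # two diploids: alleles 0,1,1,1 at one site of 10 -> (3*1)/C(4,2)/10
        vt = make_variant_table(
            {"a": [(0, 1)] + [(0, 0)] * 9, "b": [(1, 1)] + [(0, 0)] * 9}, ploidy=2
        )
        assert nucleotide_diversity(vt) == pytest.approx((3 / 6) / 10)


# ---------------------------------------------------------------------------
# divergence dating


class TestBranchFraction:
    def test_identical_strains_zero(self):
        genos = {"focal": [(0, 0, 1, 1)] * 10, "relative": [(0, 0, 1, 1)] * 10}
        vt = make_variant_table(genos, ploidy=4, syn=True)
        est = branch_fraction(vt, "focal", "relative")
        assert est.c_focal == est.c_rel == 0
        assert est.f == 0.0

    def test_hand_computed_toy(self):
        # S=100 syn sites; focal: 29 shared + 1 private fixed-alt sites
        # (dosage sum 120 -> d_pair = 0.30); relative additionally carries
        # 2 private sites
        focal, relative = [], []
        for _ in range(29):  # shared
            focal.append((1, 1, 1, 1))
            relative.append((1, 1, 1, 1))
        focal.append((1, 1, 1, 1))  # focal-private
        relative.append((0, 0, 0, 0))
        for _ in range(2):  # relative-private
            focal.append((0, 0, 0, 0))
            relative.append((1, 1, 1, 1))
        for _ in range(68):
            focal.append((0, 0, 0, 0))
            relative.append((0, 0, 0, 0))
        vt = make_variant_table({"focal": focal, "relative": relative}, ploidy=4, syn=True)
        est = branch_fraction(vt, "focal", "relative")
        assert est.S == 100
        assert (est.c_focal, est.c_rel) == (1, 2)
        assert est.d_pair == pytest.approx(0.30)
        assert est.f == pytest.approx(0.10)
        assert est.T_split == pytest.approx(est.f * est.T_out)

    def test_parameter_recovery(self):
        cfg = dict(n_syn_sites=100_000, mu=5e-9, T_outgroup=2e6, T_split=2e5)
        fs = [
            branch_fraction(
                *(simulate_population(PopSimConfig(**cfg, seed=s))[0],),
                "focal", "relative",
            ).f
            for s in range(5)
        ]
        assert np.mean(fs) == pytest.approx(0.1, rel=0.1)

    def test_label_swap_symmetric(self):
        genos = {"focal": [(1, 1, 1, 1), (0, 0, 0, 0)] * 5,
                 "relative": [(0, 0, 0, 0), (1, 1, 1, 1)] * 5}
        vt = make_variant_table(genos, ploidy=4, syn=True)
        a = branch_fraction(vt, "focal", "relative")
        b = branch_fraction(vt, "relative", "focal")
        assert a.f == pytest.approx(b.f)

    def test_no_syn_sites_error(self):
        vt = make_variant_table({"focal": [(0, 0, 0, 0)], "relative": [(0, 0, 0, 0)]},
                                ploidy=4, syn=False)
        vt.site_annotations["SYN"] = 0.0
        with pytest.raises(BrewtraceError):
            branch_fraction(vt, "focal", "relative")


class TestClock:
    def test_zero(self):
        assert clock_generations(0.0) == 0.0

    def test_one_generation(self):
        assert clock_generations(2 * MU, MU) == pytest.approx(1.0)

    def test_round_trip(self):
        T = 1.4e7
        d = 2 * MU * T
        assert clock_generations(d, MU) == pytest.approx(T)


class TestGenerationsToYears:
    def test_paper_values(self):
        assert generations_to_years(18_894) == (6, 126)

    def test_zero(self):
        assert generations_to_years(0) == (0, 0)

    def test_one_year_fast(self):
        assert generations_to_years(2920) == (1, 19)

    def test_negative_error(self):
        with pytest.raises(BrewtraceError):
            generations_to_years(-1)
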