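"""Differential-expression statistics against independent oracles.

The brute-force oracles here (rank-assignment enumeration for the
Wilcoxon test, the literal step-up definition for BH, binomial
coefficients for the hypergeometric test) are written independently of
the implementation paths they check.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from scmosaic.differential import (
    bh_adjust,
    gate_positive_cells,
    find_all_markers,
    hypergeom_enrichment,
    wilcoxon_de,
    wilcoxon_rank_sum,
)
from scmosaic.types import ScaledMatrix

from conftest import norm_from_values


def oracle_rank_sum_p(x, y):
    """Exact two-sided rank-sum p: P(|W - E[W]| >= |obs - E[W]|) by full
    enumeration of group assignments of the pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_x = len(x)
    obs = ranks[:n_x].sum()
    sums = [sum(c) for c in combinations(ranks, n_x)]
    e = float(np.mean(sums))
    dev = abs(obs - e)
    return float(np.mean([abs(s - e) >= dev - 1e-9 for s in sums]))


def oracle_bh(p):
    """Literal BH step-up: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestWilcoxonRankSum:
    def test_textbook_case_no_overlap(self):
        # A = (1,2,3), B = (4,5,6): 1 of 20 assignments as extreme, doubled
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self, rng):
        """100 random instances with group sizes <= 8, including ties."""
        for _ in range(100):
            n1, n2 = rng.integers(3, 9, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n2).astype(float)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                oracle_rank_sum_p(x, y), abs=1e-12
            )

    def test_normal_approximation_close_to_exact(self, rng):
        """Asymptotic path within 0.02 of exact enumeration at n = 5..8."""
        worst = 0.0
        for _ in range(100):
            n1, n2 = rng.integers(5, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            exact = wilcoxon_rank_sum(x, y, method="exact")
            approx = wilcoxon_rank_sum(x, y, method="asymptotic")
            worst = max(worst, abs(exact - approx))
        assert worst < 0.02

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([2, 2, 2], [2, 2, 2]) == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), oracle_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.1, 1.2])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestWilcoxonDe:
    def test_min_pct_gate_excludes_sparsely_expressed_gene(self):
        # gene expressed in 10% of cells in both groups is not tested
        vals = np.zeros((20, 2), dtype=int)
        vals[:, 1] = 1  # keeps cell totals positive
        vals[0, 0] = 5  # 10% of group A
        vals[10, 0] = 5  # 10% of group B
        norm = norm_from_values(vals)
        table = wilcoxon_de(
            norm, norm.cell_ids[:10], norm.cell_ids[10:], min_pct=0.25
        )
        assert "g0" not in set(table["gene"])

    def test_identical_groups_give_zero_lfc_high_p(self, rng):
        block = rng.integers(0, 5, size=(6, 4)) + 1
        vals = np.vstack([block, block])
        norm = norm_from_values(vals)
        table = wilcoxon_de(norm, norm.cell_ids[:6], norm.cell_ids[6:])
        assert np.allclose(table["log2_fold_change"], 0.0)
        assert (table["p_value"] >= 0.99).all()

    def test_overlapping_groups_rejected(self, rng):
        norm = norm_from_values(rng.integers(1, 5, size=(6, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            wilcoxon_de(norm, norm.cell_ids[:4], norm.cell_ids[2:])

    def test_bh_multiplicity_counts_only_tested_genes(self, rng):
        vals = rng.integers(0, 6, size=(30, 20)) + 1
        norm = norm_from_values(vals)
        table = wilcoxon_de(
            norm, norm.cell_ids[:15], norm.cell_ids[15:], logfc_threshold=0.01
        )
        # adjusted values recomputed over the tested subset only
        assert np.allclose(
            table["p_adjusted"], oracle_bh(table["p_value"].to_numpy()), atol=1e-12
        )


class TestFindAllMarkers:
    def test_two_clusters_are_mirror_images(self, rng):
        vals = rng.poisson(3.0, size=(40, 15)) + 1
        norm = norm_from_values(vals)
        clusters = pd.Series(
            ["A"] * 20 + ["B"] * 20, index=list(norm.cell_ids)
        )
        table = find_all_markers(norm, clusters, min_pct=0, logfc_threshold=0)
        a = table[table["cluster"] == "A"].set_index("gene")
        b = table[table["cluster"] == "B"].set_index("gene")
        shared = a.index.intersection(b.index)
        assert np.allclose(
            a.loc[shared, "log2_fold_change"],
            -b.loc[shared, "log2_fold_change"],
        )
        assert np.allclose(a.loc[shared, "p_value"], b.loc[shared, "p_value"])

    def test_planted_markers_recovered_with_correct_cluster(self, demo, demo_norm):
        counts, _, truth = demo
        norm, meta, _ = demo_norm
        clusters = meta.set_index("cell_id")["cluster"]
        table = find_all_markers(norm, clusters, min_pct=0.25, logfc_threshold=0.25)
        sig = table[(table["p_adjusted"] < 0.05) & (table["log2_fold_change"] > 0)]
        called = set(zip(sig["gene"], sig["cluster"]))
        planted = set(
            zip(truth.cluster_markers["gene"], truth.cluster_markers["cluster"])
        )
        assert len(planted & called) / len(planted) >= 0.9

    def test_single_cluster_rejected(self, rng):
        norm = norm_from_values(rng.integers(1, 4, size=(6, 3)))
        clusters = pd.Series(["A"] * 6, index=list(norm.cell_ids))
        with pytest.raises(ValueError, match="2 clusters"):
            find_all_markers(norm, clusters)

    def test_tiny_cluster_skipped_with_warning(self, rng, caplog):
        norm = norm_from_values(rng.integers(1, 4, size=(10, 3)))
        clusters = pd.Series(
            ["A"] * 8 + ["B"] * 2, index=list(norm.cell_ids)
        )
        with caplog.at_level("WARNING"):
            table = find_all_markers(norm, clusters, min_pct=0, logfc_threshold=0)
        assert set(table["cluster"]) == {"A"}
        assert "skipped" in caplog.text


class TestGatePositiveCells:
    @staticmethod
    def ladder_matrix():
        vals = np.arange(1.0, 11.0).reshape(-1, 1)
        return ScaledMatrix(
            vals,
            np.array([f"c{i}" for i in range(10)]),
            np.array(["Ccr2"]),
            clip_max=10.0,
        )

    def test_seventieth_percentile_by_linear_interpolation(self):
        # values 1..10: P70 = 7.3; strictly greater keeps 8, 9, 10
        scaled = self.ladder_matrix()
        got = gate_positive_cells(scaled, "Ccr2", percentile=70)
        assert set(got) == {"c7", "c8", "c9"}

    def test_percentile_zero_keeps_all_above_minimum(self):
        scaled = self.ladder_matrix()
        got = gate_positive_cells(scaled, "Ccr2", percentile=0)
        assert set(got) == {f"c{i}" for i in range(1, 10)}

    def test_constant_expression_gates_nothing(self):
        scaled = ScaledMatrix(
            np.zeros((5, 1)),
            np.array([f"c{i}" for i in range(5)]),
            np.array(["Ccr2"]),
        )
        assert len(gate_positive_cells(scaled, "Ccr2", percentile=70)) == 0

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError, match="Nope"):
            gate_positive_cells(self.ladder_matrix(), "Nope")

    def test_subset_restricts_the_reference_distribution(self):
        scaled = self.ladder_matrix()
        got = gate_positive_cells(
            scaled, "Ccr2", percentile=50, cells_subset=[f"c{i}" for i in range(4)]
        )
        assert set(got) == {"c2", "c3"}


class TestHypergeomEnrichment:
    def test_exact_binomial_coefficient_value(self):
        # universe 10, annotation 4, hits 5, overlap 3:
        # P(X >= 3) = [C(4,3)C(6,2) + C(4,4)C(6,1)] / C(10,5) = 66/252
        universe = [f"u{i}" for i in range(10)]
        annotation = universe[:4]
        hits = universe[:3] + universe[4:6]
        p, overlap = hypergeom_enrichment(hits, annotation, universe)
        assert overlap == 3
        assert p == pytest.approx(66 / 252)

    def test_matches_enumeration_oracle_on_random_universes(self, rng):
        for _ in range(100):
            m = int(rng.integers(5, 21))
            universe = [f"u{i}" for i in range(m)]
            ann = list(rng.choice(universe, size=rng.integers(1, m + 1), replace=False))
            hits = list(rng.choice(universe, size=rng.integers(1, m + 1), replace=False))
            p, k = hypergeom_enrichment(hits, ann, universe)
            n_ann, n_hit = len(ann), len(hits)
            expected = sum(
                comb(n_ann, j) * comb(m - n_ann, n_hit - j)
                for j in range(k, min(n_ann, n_hit) + 1)
            ) / comb(m, n_hit)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_with_tiny_annotation_is_near_one(self):
        universe = [f"u{i}" for i in range(100)]
        p, overlap = hypergeom_enrichment(universe[:5], universe[99:], universe)
        assert overlap == 0
        assert p == 1.0

    def test_certain_event_is_one(self):
        universe = ["a", "b", "c"]
        p, overlap = hypergeom_enrichment(universe, universe, universe)
        assert overlap == 3
        assert p == 1.0

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment(["x"], ["a"], ["a", "b"])
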