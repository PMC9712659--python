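import numpy as np
import pandas as pd
import pytest

from scmosaic.interactions import (
    lr_differential,
    lr_pair_means,
    lr_permutation_test,
    standardize_orientation,
)
from scmosaic.preprocess import lognormalize, qc_pipeline
from scmosaic.simulate import LRSpec, SimConfig, simulate_dataset
from scmosaic.types import FormatError, LRPairTable, NormMatrix

from conftest import labels_series


def norm_direct(values, genes):
    values = np.asarray(values, dtype=float)
    return NormMatrix(
        values,
        np.array([f"c{i}" for i in range(values.shape[0])]),
        np.array(genes),
    )


def pair_table(*pairs):
    return LRPairTable(
        pd.DataFrame([{"ligand": l, "receptor": r} for l, r in pairs])
    )


class TestLrPairMeans:
    def test_arithmetic_mean_of_sender_and_receiver(self):
        # ligand mean 2 in sender A, receptor mean 4 in receiver B -> 3
        norm = norm_direct(
            [[2.0, 0.0], [2.0, 0.0], [0.0, 4.0], [0.0, 4.0]], ["Ccl5", "Ccr5"]
        )
        labels = labels_series(norm.cell_ids, ["A", "A", "B", "B"])
        table = lr_pair_means(norm, labels, pair_table(("Ccl5", "Ccr5")))
        row = table.set_index(["sender", "receiver"]).loc[("A", "B")]
        assert row["pair_mean"] == pytest.approx(3.0)

    def test_zero_expression_pair_not_expressed(self):
        norm = norm_direct(
            [[0.0, 1.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]], ["Ccl5", "Filler"]
        )
        labels = labels_series(norm.cell_ids, ["A", "A", "B", "B"])
        # receptor missing from universe -> the only pair row is skipped
        with pytest.raises(ValueError, match="no ligand-receptor pair"):
            lr_pair_means(norm, labels, pair_table(("Ccl5", "Ccr5")))

    def test_unexpressed_pair_flagged(self):
        norm = norm_direct(
            [[0.0, 0.5], [0.0, 0.5], [0.0, 0.5], [0.0, 0.5]], ["Ccl5", "Ccr5"]
        )
        labels = labels_series(norm.cell_ids, ["A", "A", "B", "B"])
        table = lr_pair_means(norm, labels, pair_table(("Ccl5", "Ccr5")))
        row = table.set_index(["sender", "receiver"]).loc[("A", "B")]
        assert row["pair_mean"] == pytest.approx(0.25)
        assert not row["expressed_flag"]  # ligand never expressed

    def test_planted_axis_has_maximal_pair_mean(self, demo, demo_norm):
        _, _, truth = demo
        norm, meta, _ = demo_norm
        labels = meta.set_index("cell_id")["cluster"]
        table = lr_pair_means(norm, labels, pair_table(("Ccl5", "Ccr5")))
        best = table.loc[table["pair_mean"].idxmax()]
        planted = truth.lr_pairs.iloc[0]
        assert (best["sender"], best["receiver"]) == (
            planted["sender"],
            planted["receiver"],
        )


class TestLrPermutationTest:
    @staticmethod
    def exclusive_dataset(n_per=40):
        """Ligand exclusively in sender A, receptor exclusively in B."""
        rng = np.random.default_rng(5)
        genes = ["Ccl5", "Ccr5", "F1", "F2"]
        vals = rng.uniform(0.1, 0.3, size=(3 * n_per, 4))
        vals[:, 0] = 0.0
        vals[:, 1] = 0.0
        vals[:n_per, 0] = 3.0  # cluster A: ligand only
        vals[n_per : 2 * n_per, 1] = 3.0  # cluster B: receptor only
        norm = norm_direct(vals, genes)
        labels = labels_series(
            norm.cell_ids, ["A"] * n_per + ["B"] * n_per + ["C"] * n_per
        )
        return norm, labels

    def test_exclusive_pair_attains_minimal_grid_p(self):
        norm, labels = self.exclusive_dataset()
        table = lr_permutation_test(
            norm, labels, pair_table(("Ccl5", "Ccr5")), n_perm=200, seed=1
        )
        row = table.set_index(["sender", "receiver"]).loc[("A", "B")]
        assert row["p_value"] == pytest.approx(1 / 201)

    def test_p_values_lie_on_permutation_grid(self):
        norm, labels = self.exclusive_dataset()
        table = lr_permutation_test(
            norm, labels, pair_table(("Ccl5", "Ccr5")), n_perm=50, seed=1
        )
        p = table["p_value"].dropna().to_numpy()
        grid = np.arange(1, 52) / 51
        assert all(np.isclose(grid, v).any() for v in p)
        assert (p > 0).all()

    def test_fixed_seed_reproducible(self):
        norm, labels = self.exclusive_dataset()
        t1 = lr_permutation_test(norm, labels, pair_table(("Ccl5", "Ccr5")),
                                 n_perm=100, seed=9)
        t2 = lr_permutation_test(norm, labels, pair_table(("Ccl5", "Ccr5")),
                                 n_perm=100, seed=9)
        assert t1.equals(t2)

    def test_small_n_perm_warns(self, caplog):
        norm, labels = self.exclusive_dataset(10)
        with caplog.at_level("WARNING"):
            lr_permutation_test(norm, labels, pair_table(("Ccl5", "Ccr5")),
                                n_perm=50, seed=0)
        assert "small" in caplog.text

    def test_null_p_values_roughly_uniform(self, rng):
        """With no planted structure, permutation p over many pairs and
        cluster pairs should be approximately uniform."""
        from scipy.stats import kstest

        genes = [f"L{i}" for i in range(10)] + [f"R{i}" for i in range(10)]
        vals = rng.gamma(2.0, 0.5, size=(120, 20))
        norm = norm_direct(vals, genes)
        labels = labels_series(norm.cell_ids, ["A", "B", "C"] * 40)
        pairs = pair_table(*[(f"L{i}", f"R{i}") for i in range(10)])
        table = lr_permutation_test(norm, labels, pairs, n_perm=200, seed=2)
        p = table["p_value"].dropna().to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01


class TestLrDifferential:
    def test_identical_groups_null_result(self, rng):
        vals = rng.gamma(2.0, 0.5, size=(30, 2))
        norm_a = norm_direct(vals, ["Ccl5", "Ccr5"])
        norm_b = NormMatrix(
            vals.copy(),
            np.array([f"other{i}" for i in range(30)]),
            np.array(["Ccl5", "Ccr5"]),
        )
        table = lr_differential(norm_a, norm_b, pair_table(("Ccl5", "Ccr5")))
        assert table["log2_fold_change"].iloc[0] == pytest.approx(0.0)
        assert table["p_value"].iloc[0] > 0.9

    def test_planted_downregulated_pair_detected(self):
        """A pair 4-fold lower in the mutant is recovered with adjusted
        p < 0.05 and negative log2FC (mutant over wild-type)."""
        spec = SimConfig(
            cell_counts={("M", "WT", "none"): 400, ("M", "Mut", "none"): 400},
            n_genes=60,
            baseline_mean=1.0,
            genotype_markers=[("Ccl5", "WT", 4.0), ("Ccr5", "WT", 4.0)],
            lr_specs=[LRSpec("Ccl5", "Ccr5", "M", "M", fold=1.0)],
            n_mito_genes=2,
            seed=21,
        )
        counts, meta, _ = simulate_dataset(spec)
        norm = lognormalize(counts)
        gt = meta.set_index("cell_id")["genotype"]
        norm_mut = norm.subset_cells(gt.index[gt == "Mut"].to_numpy())
        norm_wt = norm.subset_cells(gt.index[gt == "WT"].to_numpy())
        pairs = pair_table(("Ccl5", "Ccr5"), ("F1", "F2"))
        # add two null filler pairs present in the universe
        pairs = pair_table(("Ccl5", "Ccr5"), ("Gene00001", "Gene00002"))
        table = lr_differential(norm_mut, norm_wt, pairs)
        row = table.set_index(["ligand", "receptor"]).loc[("Ccl5", "Ccr5")]
        assert row["p_adjusted"] < 0.05
        assert row["log2_fold_change"] < 0

    def test_cluster_unit_uses_cluster_means_as_observations(self, rng):
        vals = rng.gamma(2.0, 0.5, size=(40, 2))
        norm_a = norm_direct(vals, ["Ccl5", "Ccr5"])
        norm_b = NormMatrix(
            vals + 1.0,
            np.array([f"other{i}" for i in range(40)]),
            np.array(["Ccl5", "Ccr5"]),
        )
        labels_a = labels_series(norm_a.cell_ids, ["K1", "K2", "K3", "K4"] * 10)
        labels_b = labels_series(norm_b.cell_ids, ["K1", "K2", "K3", "K4"] * 10)
        table = lr_differential(
            norm_a, norm_b, pair_table(("Ccl5", "Ccr5")),
            unit="cluster", clusters_a=labels_a, clusters_b=labels_b,
        )
        # 4 vs 4 cluster means, fully separated: exact two-sided p = 2/70
        assert table["p_value"].iloc[0] == pytest.approx(2 / 70)

    def test_cluster_unit_requires_labels(self, rng):
        vals = rng.gamma(2.0, 0.5, size=(10, 2))
        norm_a = norm_direct(vals, ["Ccl5", "Ccr5"])
        with pytest.raises(ValueError, match="cluster labels"):
            lr_differential(norm_a, norm_a, pair_table(("Ccl5", "Ccr5")),
                            unit="cluster")

    def test_too_few_cells_rejected(self, rng):
        vals = rng.gamma(2.0, 0.5, size=(2, 2))
        norm_a = norm_direct(vals, ["Ccl5", "Ccr5"])
        with pytest.raises(ValueError, match="3 cells"):
            lr_differential(norm_a, norm_a, pair_table(("Ccl5", "Ccr5")))


class TestStandardizeOrientation:
    def test_receptor_first_rows_flipped(self):
        raw = pd.DataFrame(
            {
                "ligand": ["Ccr5", "Ccl7"],
                "receptor": ["Ccl5", "Ccr2"],
                "orientation": ["receptor-ligand", "ligand-receptor"],
            }
        )
        table = standardize_orientation(raw)
        assert table.pairs() == [("Ccl5", "Ccr5"), ("Ccl7", "Ccr2")]

    def test_flip_creating_duplicate_collapsed(self, caplog):
        raw = pd.DataFrame(
            {
                "ligand": ["Ccl5", "Ccr5"],
                "receptor": ["Ccr5", "Ccl5"],
                "orientation": ["ligand-receptor", "receptor-ligand"],
            }
        )
        with caplog.at_level("WARNING"):
            table = standardize_orientation(raw)
        assert table.pairs() == [("Ccl5", "Ccr5")]

    def test_unknown_orientation_rejected(self):
        raw = pd.DataFrame(
            {"ligand": ["A"], "receptor": ["B"], "orientation": ["sideways"]}
        )
        with pytest.raises(FormatError, match="sideways"):
            standardize_orientation(raw)
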