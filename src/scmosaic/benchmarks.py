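"""End-to-end calibration benchmarks with independent oracles.

Each function here exercises one statistical guarantee of the package
on synthetic data with planted truth, or against a brute-force oracle
(full enumeration, the literal step-up definition, closed-form
expectations), and returns the measured quantities. They back both the
calibration test suite and the self-check script.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import kstest, rankdata

from .differential import (
    bh_adjust,
    hypergeom_enrichment,
    wilcoxon_de,
    wilcoxon_rank_sum,
)
from .interactions import lr_differential, lr_permutation_test
from .preprocess import (
    cell_percentile_mask,
    filter_genes_min_cells,
    lognormalize,
    qc_pipeline,
    remove_doublets,
    remove_mito_genes,
)
from .regulons import differential_regulons, module_scores, regulon_activity
from .simulate import (
    LRSpec,
    RegulonSpec,
    SimConfig,
    simulate_dataset,
    simulate_paired_datasets,
)
from .specificity import (
    cross_dataset_correlation,
    recovered_correspondence,
    shared_feature_genes,
    specificity_matrix,
)
from .trajectory import TrajectoryProfile, cosine_perm_test, cosine_similarity
from .types import CountMatrix, LRPairTable, NormMatrix, Regulon


# ---------------------------------------------------------------- oracles


def oracle_rank_sum_p(x, y) -> float:
    """Exhaustive two-sided rank-sum p: P(|W - E[W]| >= |obs - E[W]|)
    over every assignment of the pooled midranks to the two groups."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_x = len(x)
    obs = ranks[:n_x].sum()
    sums = np.array([sum(c) for c in combinations(tuple(ranks), n_x)])
    e = sums.mean()
    return float(np.mean(np.abs(sums - e) >= abs(obs - e) - 1e-9))


def oracle_bh(p) -> np.ndarray:
    """Literal BH step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def oracle_hypergeom_p(overlap, m, n_ann, n_hit) -> float:
    """Upper-tail hypergeometric by explicit binomial coefficients."""
    return sum(
        comb(n_ann, j) * comb(m - n_ann, n_hit - j)
        for j in range(overlap, min(n_ann, n_hit) + 1)
    ) / comb(m, n_hit)


# ------------------------------------------------------ exact-test checks


def wilcoxon_exact_agreement(seed: int, n_instances: int = 100) -> float:
    """Max |p - oracle p| over random tied instances, group sizes <= 8."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)
        y = rng.integers(0, 6, size=n2).astype(float)
        worst = max(worst, abs(wilcoxon_rank_sum(x, y) - oracle_rank_sum_p(x, y)))
    return worst


def bh_agreement(seed: int, n_vectors: int = 1000) -> float:
    """Max |BH - brute-force step-up| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        worst = max(worst, float(np.abs(bh_adjust(p) - oracle_bh(p)).max()))
    return worst


def hypergeom_agreement(seed: int, n_instances: int = 100) -> float:
    """Max |p - enumeration| over random universes of size <= 20."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(5, 21))
        universe = [f"u{i}" for i in range(m)]
        ann = list(rng.choice(universe, size=int(rng.integers(1, m + 1)),
                              replace=False))
        hits = list(rng.choice(universe, size=int(rng.integers(1, m + 1)),
                               replace=False))
        p, k = hypergeom_enrichment(hits, ann, universe)
        worst = max(worst, abs(p - oracle_hypergeom_p(k, m, len(ann), len(hits))))
    return worst


# -------------------------------------------------- specificity-index laws


def specificity_laws(seed: int, n_datasets: int = 50) -> dict:
    """Entry bounds, uniform-gene rows, and the weighted row-mean law on
    random balanced synthetic datasets."""
    rng = np.random.default_rng(seed)
    max_excess = 0.0  # how far any entry exceeds [0, N]
    max_weighted_dev = 0.0
    max_uniform_dev = 0.0
    for _ in range(n_datasets):
        n_clusters = int(rng.integers(2, 6))
        n_per = int(rng.integers(30, 60))
        markers = [
            (f"Mk{c}_{j}", f"K{c}", float(rng.uniform(2, 10)))
            for c in range(n_clusters)
            for j in range(3)
        ]
        cfg = SimConfig(
            cell_counts={(f"K{c}", "WT", "none"): n_per for c in range(n_clusters)},
            n_genes=150,
            baseline_mean=1.0,
            cluster_markers=markers,
            n_mito_genes=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        counts, meta, _ = simulate_dataset(cfg)
        norm = lognormalize(counts)
        spec = specificity_matrix(norm, meta.set_index("cell_id")["cluster"])
        vals = spec.values.to_numpy()
        max_excess = max(
            max_excess, float(max(-vals.min(), vals.max() - n_clusters, 0.0))
        )
        w = spec.cluster_fractions.reindex(spec.values.columns).to_numpy()
        max_weighted_dev = max(
            max_weighted_dev, float(np.abs((vals * w).sum(axis=1) - 1).max())
        )
        # an exactly uniform gene scores 1 in every cluster
        uni = NormMatrix(
            np.full((n_clusters * n_per, 1), 2.0),
            norm.cell_ids,
            np.array(["Uniform"]),
        )
        uspec = specificity_matrix(uni, meta.set_index("cell_id")["cluster"])
        max_uniform_dev = max(
            max_uniform_dev, float(np.abs(uspec.values.to_numpy() - 1).max())
        )
    return {
        "entry_bound_excess": max_excess,
        "weighted_row_mean_max_dev": max_weighted_dev,
        "uniform_gene_max_dev": max_uniform_dev,
    }


# --------------------------------------- cross-dataset correspondence


def correspondence_recovery(
    seed: int, n_replicates: int = 20, n_clusters: int = 5
) -> float:
    """Fraction of replicates where the per-row argmax of the Spearman
    correspondence matrix recovers the full planted cluster mapping."""
    rng = np.random.default_rng(seed)
    base = SimConfig(
        cell_counts={("X", "WT", "none"): 100},
        n_genes=400,
        baseline_mean=0.5,
        n_mito_genes=2,
        seed=0,
    )
    hits = 0
    for _ in range(n_replicates):
        (ca, ma), (cb, mb), truth = simulate_paired_datasets(
            base, n_clusters, seed=int(rng.integers(0, 2**31 - 1))
        )
        na, ma2, _ = qc_pipeline(ca, ma)
        nb, mb2, _ = qc_pipeline(cb, mb)
        shared = shared_feature_genes(na, nb, n_top=200)
        sa = specificity_matrix(na, ma2.set_index("cell_id")["cluster"])
        sb = specificity_matrix(nb, mb2.set_index("cell_id")["cluster"])
        shared = [g for g in shared
                  if g in sa.values.index and g in sb.values.index]
        corr = cross_dataset_correlation(sa, sb, shared)
        got = recovered_correspondence(corr).set_index("cluster_a")["cluster_b"]
        expect = truth.set_index("cluster_a")["cluster_b"]
        hits += int(got.sort_index().equals(expect.sort_index()))
    return hits / n_replicates


# ------------------------------------------------ regulon AUC calibration


def regulon_auc_calibration(
    seed: int, n_replicates: int = 5, n_random_sets: int = 1000
) -> dict:
    """Planted-active separation and random-set mean against the
    uniform-rank closed form."""
    rng = np.random.default_rng(seed)
    worst_p = 0.0
    for _ in range(n_replicates):
        reg = Regulon("Prog", [f"RegT{j:02d}" for j in range(25)])
        cfg = SimConfig(
            cell_counts={
                ("On", "WT", "none"): 100,
                ("Off", "WT", "none"): 100,
            },
            n_genes=500,
            baseline_mean=0.5,
            regulon_specs=[RegulonSpec(reg, fold=4.0, clusters=("On",))],
            n_mito_genes=2,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        counts, meta, _ = simulate_dataset(cfg)
        norm = lognormalize(counts)
        act = regulon_activity(norm, [reg], seed=seed)
        s = act.scores["Prog"]
        on = meta.set_index("cell_id")["cluster"].reindex(s.index) == "On"
        # one-sided: active cluster scores higher
        two_sided = wilcoxon_rank_sum(
            s[on.to_numpy()].to_numpy(), s[~on.to_numpy()].to_numpy(),
            method="asymptotic",
        )
        p_one = two_sided / 2 if s[on.to_numpy()].mean() > s[~on.to_numpy()].mean() else 1.0
        worst_p = max(worst_p, p_one)

    # random gene sets vs closed-form expectation under uniform ranks
    cfg = SimConfig(
        cell_counts={("K", "WT", "none"): 40},
        n_genes=400,
        baseline_mean=1.0,
        n_mito_genes=0,
        seed=seed,
    )
    counts, _, _ = simulate_dataset(cfg)
    norm = lognormalize(counts)
    n, m = norm.n_genes, 20
    k = int(np.ceil(0.05 * n))
    expected = m * k * (k + 1) / (2 * n) / (m * k - m * (m - 1) / 2)
    sets = [
        Regulon(
            f"R{i}",
            [str(g) for g in rng.choice(norm.gene_ids, size=m, replace=False)],
        )
        for i in range(n_random_sets)
    ]
    act = regulon_activity(norm, sets, top_fraction=0.05, seed=seed)
    mc_mean = float(act.scores.to_numpy().mean())
    mc_se = float(
        act.scores.to_numpy().mean(axis=0).std(ddof=1) / np.sqrt(n_random_sets)
    )
    return {
        "active_vs_inactive_worst_p": worst_p,
        "random_set_mean": mc_mean,
        "random_set_expected": float(expected),
        "random_set_abs_error": abs(mc_mean - expected),
        "random_set_mc_se": mc_se,
    }


# -------------------------------------------- differential-regulon ledger


def regulon_ledger_recovery(seed: int, n_replicates: int = 10) -> dict:
    """50 regulons, 10 planted genotype-differential: mean recovered and
    mean false passes per replicate."""
    rng = np.random.default_rng(seed)
    recovered, false_passes = [], []
    n_regs, n_diff, size = 50, 10, 20
    for _ in range(n_replicates):
        regs = [
            Regulon(f"R{i:02d}", [f"T{i:02d}_{j:02d}" for j in range(size)])
            for i in range(n_regs)
        ]
        specs = [
            RegulonSpec(regs[i], fold=2.5 if i < n_diff else 1.0,
                        genotypes=("WT",) if i < n_diff else None)
            for i in range(n_regs)
        ]
        cfg = SimConfig(
            cell_counts={
                ("M", "WT", "none"): 150,
                ("M", "Mut", "none"): 150,
            },
            n_genes=5000,
            baseline_mean=0.5,
            # realistic transcriptome-wide spread of baseline means and a
            # modest (200 / 5000 genes) differential load, so
            # expression-matched control bins mix planted and null genes
            gene_mean_sigma=1.0,
            regulon_specs=specs,
            n_mito_genes=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        counts, meta, truth = simulate_dataset(cfg)
        norm = lognormalize(counts)
        gt = meta.set_index("cell_id")["genotype"]
        de = wilcoxon_de(
            norm,
            gt.index[gt == "WT"].to_numpy(),
            gt.index[gt == "Mut"].to_numpy(),
            min_pct=0.1,
        )
        ms = module_scores(norm, regs, seed=seed)
        ledger = differential_regulons(ms, gt, de, regs)
        passed = set(ledger.loc[ledger["pass_flag"], "regulon"])
        diff_true = set(truth.regulons.loc[truth.regulons["differential"], "tf"])
        recovered.append(len(passed & diff_true))
        false_passes.append(len(passed - diff_true))
    return {
        "mean_recovered_of_10": float(np.mean(recovered)),
        "mean_false_passes": float(np.mean(false_passes)),
    }


# --------------------------------------------- ligand-receptor calibration


def _exclusive_lr_dataset(seed: int, n_per: int = 40):
    rng = np.random.default_rng(seed)
    genes = ["Ccl5", "Ccr5", "F1", "F2"]
    vals = rng.uniform(0.1, 0.3, size=(3 * n_per, 4))
    vals[:, 0] = 0.0
    vals[:, 1] = 0.0
    vals[:n_per, 0] = 3.0
    vals[n_per: 2 * n_per, 1] = 3.0
    norm = NormMatrix(
        vals,
        np.array([f"c{i}" for i in range(3 * n_per)]),
        np.array(genes),
    )
    labels = pd.Series(
        ["A"] * n_per + ["B"] * n_per + ["C"] * n_per, index=list(norm.cell_ids)
    )
    return norm, labels


def lr_calibration(seed: int, n_replicates: int = 20, n_perm: int = 200) -> dict:
    """Null uniformity, exclusive-pair minimal p, and planted 4-fold
    differential-pair detection rate."""
    rng = np.random.default_rng(seed)

    # null: no planted structure, many pairs
    n_lr = 12
    genes = [f"L{i}" for i in range(n_lr)] + [f"R{i}" for i in range(n_lr)]
    cfg = SimConfig(
        cell_counts={(c, "WT", "none"): 60 for c in ("A", "B", "C")},
        n_genes=60,
        baseline_mean=1.0,
        cluster_markers=[(g, "A", 1.0) for g in genes],  # places genes in universe
        n_mito_genes=0,
        seed=seed,
    )
    counts, meta, _ = simulate_dataset(cfg)
    norm = lognormalize(counts)
    pairs = LRPairTable(
        pd.DataFrame(
            [{"ligand": f"L{i}", "receptor": f"R{i}"} for i in range(n_lr)]
        )
    )
    table = lr_permutation_test(
        norm, meta.set_index("cell_id")["cluster"], pairs, n_perm=n_perm, seed=seed
    )
    null_p = table["p_value"].dropna().to_numpy()
    null_ks_p = float(kstest(null_p, "uniform").pvalue)

    # exclusive sender -> receiver pair hits the minimal grid p
    norm_x, labels_x = _exclusive_lr_dataset(seed)
    ex = lr_permutation_test(
        norm_x,
        labels_x,
        LRPairTable(pd.DataFrame([{"ligand": "Ccl5", "receptor": "Ccr5"}])),
        n_perm=n_perm,
        seed=seed,
    )
    exclusive_p = float(
        ex.set_index(["sender", "receiver"]).loc[("A", "B"), "p_value"]
    )

    # planted 4-fold differential pair detection
    detected = 0
    for _ in range(n_replicates):
        cfg = SimConfig(
            cell_counts={("M", "WT", "none"): 400, ("M", "Mut", "none"): 400},
            n_genes=60,
            baseline_mean=1.0,
            genotype_markers=[("Ccl5", "WT", 4.0), ("Ccr5", "WT", 4.0)],
            lr_specs=[LRSpec("Ccl5", "Ccr5", "M", "M", fold=1.0)],
            n_mito_genes=2,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        counts, meta, _ = simulate_dataset(cfg)
        norm = lognormalize(counts)
        gt = meta.set_index("cell_id")["genotype"]
        norm_mut = norm.subset_cells(gt.index[gt == "Mut"].to_numpy())
        norm_wt = norm.subset_cells(gt.index[gt == "WT"].to_numpy())
        test_pairs = LRPairTable(
            pd.DataFrame(
                [
                    {"ligand": "Ccl5", "receptor": "Ccr5"},
                    {"ligand": "Gene00001", "receptor": "Gene00002"},
                    {"ligand": "Gene00003", "receptor": "Gene00004"},
                ]
            )
        )
        diff = lr_differential(norm_mut, norm_wt, test_pairs)
        row = diff.set_index(["ligand", "receptor"]).loc[("Ccl5", "Ccr5")]
        detected += int(
            row["p_adjusted"] < 0.05 and row["log2_fold_change"] < 0
        )
    return {
        "null_ks_p": null_ks_p,
        "exclusive_pair_p": exclusive_p,
        "minimal_grid_p": 1.0 / (n_perm + 1),
        "differential_detection_rate": detected / n_replicates,
    }


# --------------------------------------------------- trajectory calibration


def trajectory_calibration(seed: int, n_replicates: int = 200) -> dict:
    """Permutation-p uniformity under independent-noise profiles, plus
    the hand-checkable cosine of (1,2,3) vs (3,2,1)."""
    rng = np.random.default_rng(seed)

    def prof(v):
        return TrajectoryProfile(
            "g", len(v), np.asarray(v, float), np.ones(len(v), int),
            np.linspace(0, 1, len(v) + 1),
        )

    ps = []
    for _ in range(n_replicates):
        a = prof(rng.normal(size=10))
        b = prof(rng.normal(size=10))
        ps.append(
            cosine_perm_test(a, b, n_perm=99,
                             seed=int(rng.integers(0, 2**31 - 1))).p_value
        )
    return {
        "null_ks_p": float(kstest(ps, "uniform").pvalue),
        "cosine_example": cosine_similarity([1, 2, 3], [3, 2, 1]),
    }


# --------------------------------------------------------- QC determinism


def qc_determinism(seed: int) -> dict:
    """Filters at the standard thresholds remove exactly the planted
    violations on a fixture with known truth flags."""
    rng = np.random.default_rng(seed)
    n_normal, n_low, n_high = 54, 3, 3
    n_cells = n_normal + n_low + n_high
    genes = [f"g{j}" for j in range(20)] + ["rare1", "rare2", "mt-Co1"]
    n_genes = len(genes)

    vals = np.zeros((n_cells, n_genes), dtype=int)
    vals[:, :20] = 5  # identical cells: total 100, 20 features
    vals[:, 22] = 2  # the mitochondrial gene, expressed everywhere
    # rare genes detected in < 10 normal cells each; the gene filter runs
    # first, so after their removal all normal cells are again identical
    rare_cells = rng.choice(np.arange(n_normal), size=9, replace=False)
    vals[rare_cells[:5], 20] = 1
    vals[rare_cells[5:], 21] = 1
    # planted percentile violations
    vals[n_normal: n_normal + n_low, :20] = 1  # totals 20
    vals[n_normal + n_low:, :20] = 50  # totals 1000
    counts = CountMatrix(
        vals, np.array([f"c{i}" for i in range(n_cells)]), np.array(genes)
    )
    # planted doublets among the normal cells
    scores = np.full(n_cells, 0.1)
    doublet_cells = [3, 17, 30, 44]
    scores[doublet_cells] = 0.8
    meta = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "cluster": "K",
            "genotype": "WT",
            "treatment": "none",
            "doublet_score": scores,
        }
    )

    truth_gene_removed = {"rare1", "rare2"}
    truth_mito_removed = {"mt-Co1"}
    truth_cell_removed = {
        f"c{i}" for i in range(n_normal, n_cells)
    } | {f"c{i}" for i in doublet_cells}

    g1 = filter_genes_min_cells(counts, 10)
    gene_removed = set(counts.gene_ids) - set(g1.gene_ids)
    keep = cell_percentile_mask(g1, 10, 90)
    c1 = g1.subset_cells(keep)
    c2 = remove_doublets(c1, meta, 0.5)
    cell_removed = set(counts.cell_ids) - set(c2.cell_ids)
    c3 = remove_mito_genes(c2)
    mito_removed = set(c2.gene_ids) - set(c3.gene_ids)

    return {
        "gene_filter_mismatches": len(gene_removed ^ truth_gene_removed),
        "cell_filter_mismatches": len(cell_removed ^ truth_cell_removed),
        "mito_filter_mismatches": len(mito_removed ^ truth_mito_removed),
    }
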