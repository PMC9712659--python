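"""Regulon activity scoring and the differential-regulon ledger.

Two per-cell activity scores are provided:

* rank-AUC — genes are ranked per cell by decreasing expression and
  the regulon's recovery curve is integrated over the top fraction of
  the ranking (the AUCell statistic); scores lie in [0, 1];
* module score — mean expression of the gene set minus mean expression
  of expression-matched control genes drawn from average-expression
  bins (the AddModuleScore statistic); signed.

Differential regulons between two conditions are called on module
scores with a two-sided Wilcoxon test and BH correction, then filtered
by the three-criterion ledger: mean score > 0, at least one DEG among
the targets, and a DEG fraction of at least 5% of the regulon size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import bh_adjust, wilcoxon_rank_sum
from .types import GeneSet, NormMatrix, Regulon

logger = logging.getLogger("scmosaic")


@dataclass
class RegulonActivity:
    """Cells × regulons AUC scores with the recovery-window fraction."""

    scores: pd.DataFrame  # index cell_ids, columns regulon TFs
    top_fraction: float


@dataclass
class ModuleScoreTable:
    """Cells × gene-sets module scores plus the sampling parameters."""

    scores: pd.DataFrame
    n_bins: int
    n_ctrl: int
    seed: int


def _cellwise_ranks(values: np.ndarray, seed: int) -> np.ndarray:
    """0-based rank of every gene within each cell, by decreasing
    expression; ties broken by one seeded gene-order permutation shared
    across cells (deterministic)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(values.shape[1])
    shuffled = values[:, perm]
    order = np.argsort(-shuffled, axis=1, kind="stable")
    ranks_shuffled = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    ranks_shuffled[rows, order] = np.arange(values.shape[1])[None, :]
    ranks = np.empty_like(ranks_shuffled)
    ranks[:, perm] = ranks_shuffled
    return ranks


def regulon_auc(
    norm: NormMatrix,
    regulon: Regulon | GeneSet,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Per-cell rank-AUC activity of one regulon.

    The recovery curve counts regulon targets among the top-i ranked
    genes for i = 1..k, k = ceil(top_fraction * n_genes); the score is
    its area divided by the maximum achievable area, so it lies in
    [0, 1] with 1 = all targets at the very top of the ranking.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    targets = regulon.targets if isinstance(regulon, Regulon) else regulon.genes
    cols = [i for i, g in enumerate(norm.gene_ids) if g in set(targets)]
    if not cols:
        raise ValueError("no regulon targets present in the gene universe")
    k = int(np.ceil(top_fraction * norm.n_genes))
    ranks = _cellwise_ranks(norm.values, seed)[:, cols]  # cells x targets
    m = min(len(cols), k)
    # a target at 1-based rank j <= k contributes (k - j + 1) to the area
    contrib = np.clip(k - ranks, 0, None)  # ranks are 0-based: k - j + 1
    area = contrib.sum(axis=1)
    max_area = m * k - m * (m - 1) // 2
    return pd.Series(area / max_area, index=norm.cell_ids, name=_set_name(regulon))


def _set_name(regulon) -> str:
    return regulon.tf if isinstance(regulon, Regulon) else regulon.name


def regulon_activity(
    norm: NormMatrix, regulons, top_fraction: float = 0.05, seed: int = 0
) -> RegulonActivity:
    """AUC scores for a collection of regulons (shared ranking pass)."""
    ranks = _cellwise_ranks(norm.values, seed)
    k = int(np.ceil(top_fraction * norm.n_genes))
    gpos = {g: i for i, g in enumerate(norm.gene_ids)}
    out = {}
    for reg in regulons:
        targets = reg.targets if isinstance(reg, Regulon) else reg.genes
        cols = [gpos[g] for g in targets if g in gpos]
        if not cols:
            logger.warning("regulon %r has no targets in universe; skipped",
                           _set_name(reg))
            continue
        m = min(len(cols), k)
        contrib = np.clip(k - ranks[:, cols], 0, None)
        out[_set_name(reg)] = contrib.sum(axis=1) / (m * k - m * (m - 1) // 2)
    return RegulonActivity(
        pd.DataFrame(out, index=norm.cell_ids), top_fraction
    )


def module_score(
    norm: NormMatrix,
    gene_set: GeneSet | Regulon,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched signature score per cell.

    All genes are binned into n_bins by dataset-average expression; for
    each signature gene, n_ctrl control genes are drawn (with
    replacement, seeded) from its bin. The score is the mean expression
    of the signature genes minus the mean expression of the pooled
    controls, per cell — 0 in expectation for a random gene set.
    """
    genes = gene_set.targets if isinstance(gene_set, Regulon) else gene_set.genes
    gpos = {g: i for i, g in enumerate(norm.gene_ids)}
    cols = [gpos[g] for g in genes if g in gpos]
    if not cols:
        raise ValueError("gene set has no genes in the universe")
    avg = norm.values.mean(axis=0)
    # equal-frequency bins on average expression (rank-based cut)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(norm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(norm.n_genes) * n_bins) // norm.n_genes, n_bins - 1
    )
    rng = np.random.default_rng(seed)
    ctrl_cols = []
    for c in cols:
        pool = np.flatnonzero(bins == bins[c])
        ctrl_cols.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_cols = np.concatenate(ctrl_cols)
    score = norm.values[:, cols].mean(axis=1) - norm.values[:, ctrl_cols].mean(axis=1)
    return pd.Series(score, index=norm.cell_ids, name=_set_name(gene_set))


def module_scores(
    norm: NormMatrix, gene_sets, n_bins: int = 24, n_ctrl: int = 100, seed: int = 0
) -> ModuleScoreTable:
    cols = {}
    for gs in gene_sets:
        try:
            cols[_set_name(gs)] = module_score(norm, gs, n_bins, n_ctrl, seed)
        except ValueError:
            logger.warning("gene set %r has no genes in universe; skipped",
                           _set_name(gs))
    return ModuleScoreTable(pd.DataFrame(cols), n_bins, n_ctrl, seed)


def differential_regulons(
    scores: ModuleScoreTable,
    condition_labels: pd.Series,
    de_table: pd.DataFrame,
    regulons,
    alpha: float = 0.05,
    min_deg_fraction: float = 0.05,
) -> pd.DataFrame:
    """The differential-regulon ledger between exactly two conditions.

    Per regulon: two-sided Wilcoxon on per-cell module scores between
    the conditions, BH over regulons, then pass_flag =
    (adjusted p < alpha) AND (the regulon is expressed: mean score > 0
    in at least one condition) AND (>= 1 DEG among targets) AND
    (DEG fraction >= min_deg_fraction of the regulon size). DEGs are
    de_table rows with p_adjusted < alpha. Sorted by adjusted p.
    """
    labels = condition_labels.reindex(scores.scores.index)
    if labels.isna().any():
        raise ValueError("condition label missing for some cells")
    conds = sorted(labels.unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    degs = set(de_table.loc[de_table["p_adjusted"] < alpha, "gene"])
    mask_a = (labels == conds[0]).to_numpy()
    mask_b = (labels == conds[1]).to_numpy()

    rows = []
    by_name = {_set_name(r): r for r in regulons}
    for name in scores.scores.columns:
        if name not in by_name:
            continue
        reg = by_name[name]
        vec = scores.scores[name].to_numpy()
        s_a, s_b = vec[mask_a], vec[mask_b]
        p = wilcoxon_rank_sum(s_a, s_b)
        targets = reg.targets if isinstance(reg, Regulon) else reg.genes
        n_deg = len(set(targets) & degs)
        size = len(targets)
        rows.append(
            {
                "regulon": name,
                f"mean_score_{conds[0]}": s_a.mean(),
                f"mean_score_{conds[1]}": s_b.mean(),
                "score_difference": s_a.mean() - s_b.mean(),
                "mean_score": vec.mean(),
                "max_condition_mean": max(s_a.mean(), s_b.mean()),
                "p_value": p,
                "regulon_size": size,
                "n_deg_targets": n_deg,
                "deg_fraction": n_deg / size if size else 0.0,
            }
        )
    ledger = pd.DataFrame(rows)
    if ledger.empty:
        raise ValueError("no scored regulons to test")
    ledger["p_adjusted"] = bh_adjust(ledger["p_value"].to_numpy())
    ledger["pass_flag"] = (
        (ledger["p_adjusted"] < alpha)
        & (ledger["max_condition_mean"] > 0)
        & (ledger["n_deg_targets"] >= 1)
        & (ledger["deg_fraction"] >= min_deg_fraction)
    )
    return ledger.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
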