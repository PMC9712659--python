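"""Wilcoxon rank-sum differential expression and related tests.

The two-sided Wilcoxon rank-sum test uses the normal approximation
with midranks and tie correction; when both groups have at most 8
observations it switches to exact enumeration over all group
assignments of the pooled values (correct under ties, unlike the
standard no-ties exact null). Multiplicity is controlled with
Benjamini-Hochberg over the genes that pass the min.pct / log-fold
gates, so the correction factor equals the number of genes actually
tested.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import NormMatrix, ScaledMatrix

logger = logging.getLogger("scmosaic")

EXACT_MAX_N = 8


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    method="auto" uses exact enumeration when both samples have <= 8
    observations and the normal approximation with midrank tie
    correction and continuity correction otherwise; "exact" and
    "asymptotic" force one path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    if method == "auto":
        method = (
            "exact"
            if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
            else "asymptotic"
        )
    if method == "exact":
        return _exact_rank_sum_p(x, y)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all assignments of the pooled
    sample to the two groups (valid under ties, where midranks make the
    standard no-ties null incorrect): p = P(|W - E[W]| >= |obs - E[W]|)
    over the enumeration null."""
    pooled = np.concatenate([x, y])
    ranks = tuple(stats.rankdata(pooled))  # midranks
    n_x = len(x)
    obs = sum(ranks[:n_x])
    expect = len(x) * sum(ranks) / len(ranks)
    dev = abs(obs - expect)
    total = hits = 0
    for idx in combinations(ranks, n_x):
        total += 1
        if abs(sum(idx) - expect) >= dev - 1e-9:
            hits += 1
    return hits / total


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_log2fc(x: np.ndarray, y: np.ndarray, pseudocount: float = 1.0) -> float:
    """log2 fold change of de-logged means with a pseudocount:
    log2((mean(expm1 x) + pc) / (mean(expm1 y) + pc))."""
    return float(
        np.log2(
            (np.expm1(x).mean() + pseudocount) / (np.expm1(y).mean() + pseudocount)
        )
    )


def wilcoxon_de(
    norm: NormMatrix,
    cells_a,
    cells_b,
    min_pct: float = 0.0,
    logfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Gene-level differential expression between two cell groups.

    Genes enter the test only when max(pct_a, pct_b) >= min_pct and
    |log2FC| >= logfc_threshold; BH adjustment is computed over the
    tested genes. Returns one row per tested gene with columns
    gene, log2_fold_change, pct_group1, pct_group2, p_value, p_adjusted.
    """
    a = norm.subset_cells(cells_a).values
    b = norm.subset_cells(cells_b).values
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty group")
    arr_a, arr_b = np.asarray(cells_a), np.asarray(cells_b)
    if arr_a.dtype == bool and arr_b.dtype == bool:
        if np.any(arr_a & arr_b):
            raise ValueError("groups must be disjoint")
    elif set(map(str, arr_a)) & set(map(str, arr_b)):
        raise ValueError("groups must be disjoint")

    pct_a = (a > 0).mean(axis=0)
    pct_b = (b > 0).mean(axis=0)
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    idx = np.flatnonzero(tested)
    pvals = np.array([wilcoxon_rank_sum(a[:, j], b[:, j]) for j in idx])
    out = pd.DataFrame(
        {
            "gene": norm.gene_ids[idx],
            "log2_fold_change": lfc[idx],
            "pct_group1": pct_a[idx],
            "pct_group2": pct_b[idx],
            "p_value": pvals,
            "p_adjusted": bh_adjust(pvals) if len(pvals) else pvals,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def find_all_markers(
    norm: NormMatrix,
    clusters: pd.Series | dict,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cluster, concatenated with a
    cluster column. Clusters with fewer than 3 cells are skipped with
    a warning."""
    labels = pd.Series(clusters)
    labels.index = np.asarray(labels.index, dtype=object)
    labels = labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster label missing for some cells")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    frames = []
    for clu in uniq:
        in_c = labels.index[labels == clu].to_numpy()
        rest = labels.index[labels != clu].to_numpy()
        if len(in_c) < 3:
            logger.warning("cluster %r has < 3 cells; skipped", clu)
            continue
        tab = wilcoxon_de(norm, in_c, rest, min_pct, logfc_threshold)
        tab.insert(0, "cluster", clu)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def gate_positive_cells(
    scaled: ScaledMatrix,
    gene: str,
    percentile: float = 70.0,
    cells_subset=None,
) -> np.ndarray:
    """Cells whose scaled expression of `gene` lies strictly above the
    given percentile of the expression distribution over the subset.

    This is the marker-positivity gate (e.g. Ccr2+ macrophages at the
    70th percentile of scaled Ccr2).
    """
    vec = scaled.gene_vector(gene)
    ids = scaled.cell_ids
    if cells_subset is not None:
        subset = np.asarray(cells_subset, dtype=object)
        if len(subset) == 0:
            raise ValueError("empty cell subset")
        pos = {c: i for i, c in enumerate(ids)}
        sel = np.array([pos[c] for c in subset])
        vec, ids = vec[sel], ids[sel]
    threshold = np.percentile(vec, percentile)
    return ids[vec > threshold]


def hypergeom_enrichment(hits, annotation, universe) -> tuple[float, int]:
    """Upper-tail hypergeometric enrichment P(X >= overlap).

    hits and annotation must be subsets of the universe; returns
    (p_value, overlap count).
    """
    hits, annotation, universe = set(hits), set(annotation), set(universe)
    if not hits <= universe:
        raise ValueError("hit genes outside the universe")
    if not annotation <= universe:
        raise ValueError("annotation genes outside the universe")
    overlap = len(hits & annotation)
    m, n_ann, n_hits = len(universe), len(annotation), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, m, n_ann, n_hits))
    return min(p, 1.0), overlap
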