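"""QC, normalization, scaling and variable-gene selection.

The pipeline order is fixed: gene filter → cell percentile filter →
doublet removal → mitochondrial-gene removal → log-normalization →
per-gene scaling. Filters are computed on the raw matrix and applied
jointly, not sequentially re-estimated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CountMatrix, NormMatrix, ScaledMatrix

logger = logging.getLogger("scmosaic")


def filter_genes_min_cells(counts: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep genes detected (count > 0) in at least `min_cells` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    detected = (counts.values > 0).sum(axis=0)
    keep = detected >= min_cells
    logger.info("gene filter: %d/%d genes retained", int(keep.sum()), counts.n_genes)
    return counts.subset_genes(keep)


def cell_percentile_mask(
    counts: CountMatrix,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    mode: str = "union",
) -> np.ndarray:
    """Boolean keep-mask for the percentile cell filter.

    A cell is removed when its total counts or its detected-feature
    number falls outside the inclusive [P_lower, P_upper] band of the
    pre-filter distribution (percentiles by linear interpolation).
    mode="union" removes a cell if EITHER metric is out of range;
    mode="intersection" only if BOTH are.
    """
    if counts.n_cells == 0:
        raise ValueError("empty matrix")
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower < upper <= 100")
    totals = counts.values.sum(axis=1)
    n_features = (counts.values > 0).sum(axis=1)

    def in_band(x):
        lo, hi = np.percentile(x, [lower_pct, upper_pct])
        return (x >= lo) & (x <= hi)

    ok_t, ok_f = in_band(totals), in_band(n_features)
    if mode == "union":
        keep = ok_t & ok_f
    elif mode == "intersection":
        keep = ok_t | ok_f
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return keep


def filter_cells_percentile(
    counts: CountMatrix,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    mode: str = "union",
) -> CountMatrix:
    keep = cell_percentile_mask(counts, lower_pct, upper_pct, mode)
    logger.info("cell filter: %d/%d cells retained", int(keep.sum()), counts.n_cells)
    return counts.subset_cells(keep)


def remove_doublets(
    counts: CountMatrix, meta: pd.DataFrame, threshold: float = 0.5
) -> CountMatrix:
    """Remove cells whose doublet score is strictly greater than the
    threshold; a score exactly at the threshold is retained."""
    if "doublet_score" not in meta.columns:
        raise ValueError("metadata has no doublet_score column")
    scores = meta.set_index("cell_id")["doublet_score"].reindex(counts.cell_ids)
    if scores.isna().any():
        raise ValueError("doublet_score missing for some cells")
    keep = ~(scores.to_numpy() > threshold)
    logger.info(
        "doublet filter: removed %d/%d cells", int((~keep).sum()), counts.n_cells
    )
    return counts.subset_cells(keep)


def remove_mito_genes(counts: CountMatrix, prefix: str = "mt-") -> CountMatrix:
    """Drop genes whose symbol starts with the mitochondrial prefix
    (case-insensitive, so both mouse mt- and human MT- match)."""
    pref = prefix.lower()
    keep = np.array(
        [not str(g).lower().startswith(pref) for g in counts.gene_ids], dtype=bool
    )
    return counts.subset_genes(keep)


def lognormalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormMatrix:
    """Log-normalize: entry = ln(1 + count / cell_total * scale_factor)."""
    totals = counts.values.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ValueError(
            "cells with zero total count present; apply cell filtering first"
        )
    vals = np.log1p(counts.values / totals[:, None] * scale_factor)
    return NormMatrix(vals, counts.cell_ids, counts.gene_ids, scale_factor)


def scale_genes(norm: NormMatrix, clip_max: float = 10.0) -> ScaledMatrix:
    """Per-gene z-score with the sample (n-1) standard deviation,
    clipped to ±clip_max; genes with zero variance map to all-zero."""
    if norm.n_cells < 2:
        raise ValueError("scaling requires at least 2 cells")
    mean = norm.values.mean(axis=0)
    sd = norm.values.std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    z = (norm.values - mean) / safe
    z[:, sd == 0] = 0.0
    z = np.clip(z, -clip_max, clip_max)
    return ScaledMatrix(z, norm.cell_ids, norm.gene_ids, clip_max)


def select_variable_genes(norm: NormMatrix, n_top: int = 5000) -> list[str]:
    """Rank genes by mean-variance-trend residual and return the top set.

    A degree-2 polynomial of log10(variance) on log10(mean) is fit over
    genes with positive mean; genes are ranked by the residual of their
    observed log-variance above the fitted trend. Zero-variance genes
    are never selected ahead of variable ones.
    """
    mean = norm.values.mean(axis=0)
    var = norm.values.var(axis=0, ddof=1)
    pos = (mean > 0) & (var > 0)
    if int(pos.sum()) < 10:
        raise ValueError("fewer than 10 genes with positive mean expression")
    n_top = min(n_top, norm.n_genes)
    if n_top > norm.n_genes:
        raise ValueError("n_top exceeds number of genes")
    lm, lv = np.log10(mean[pos]), np.log10(var[pos])
    coef = np.polyfit(lm, lv, deg=2)
    resid = lv - np.polyval(coef, lm)
    score = np.full(norm.n_genes, -np.inf)
    score[pos] = resid
    order = np.argsort(-score, kind="stable")
    return [str(g) for g in norm.gene_ids[order[:n_top]]]


def qc_pipeline(
    counts: CountMatrix,
    meta: pd.DataFrame,
    min_cells: int = 10,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    doublet_threshold: float = 0.5,
    mito_prefix: str = "mt-",
    scale_factor: float = 10_000.0,
    cell_filter_mode: str = "union",
):
    """Run the full QC chain and return (NormMatrix, filtered meta, log).

    The log dict records entity counts after each stage for the
    pipeline manifest.
    """
    log = {"input_cells": counts.n_cells, "input_genes": counts.n_genes}
    counts = filter_genes_min_cells(counts, min_cells)
    log["genes_after_min_cells"] = counts.n_genes
    counts = filter_cells_percentile(counts, lower_pct, upper_pct, cell_filter_mode)
    log["cells_after_percentile"] = counts.n_cells
    if "doublet_score" in meta.columns:
        counts = remove_doublets(counts, meta, doublet_threshold)
    log["cells_after_doublets"] = counts.n_cells
    counts = remove_mito_genes(counts, mito_prefix)
    log["genes_after_mito"] = counts.n_genes
    norm = lognormalize(counts, scale_factor)
    kept = set(counts.cell_ids)
    meta = meta[meta["cell_id"].isin(kept)].reset_index(drop=True)
    return norm, meta, log
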