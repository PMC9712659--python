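"""Cluster gene-specificity indices and cross-dataset correspondence.

The specificity index of gene g in cluster c is the ratio of its mean
expression over the cells of c to its mean expression over all cells.
A uniformly expressed gene scores 1 in every cluster; a gene expressed
in a single cluster scores up to N (the number of clusters, exactly N
for balanced clusters). Two datasets are compared by Spearman
correlation of their specificity columns over a shared gene set —
rank-based, so any monotone per-gene transform applied to both
datasets leaves the correspondence unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import select_variable_genes
from .types import NormMatrix

logger = logging.getLogger("scmosaic")


@dataclass
class SpecificityMatrix:
    """Genes × clusters specificity indices with cluster cell fractions."""

    values: pd.DataFrame  # index genes, columns cluster labels
    cluster_fractions: pd.Series

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]


def specificity_matrix(norm, clusters) -> SpecificityMatrix:
    """Per-gene cluster specificity, by default on log-normalized
    expression (a raw CountMatrix may be passed to compute the index on
    counts instead).

    Genes with zero overall mean carry no specificity information and
    are dropped with a warning. The cell-fraction-weighted mean of each
    retained row is exactly 1.
    """
    labels = pd.Series(clusters)
    labels.index = np.asarray(labels.index, dtype=object)
    labels = labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster label missing for some cells")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")

    overall = norm.values.mean(axis=0)
    keep = overall > 0
    if not keep.all():
        logger.warning(
            "%d genes with zero overall mean dropped from specificity",
            int((~keep).sum()),
        )
    vals = norm.values[:, keep]
    cols = {}
    fractions = {}
    lab_arr = labels.to_numpy()
    for clu in uniq:
        mask = lab_arr == clu
        cols[clu] = vals[mask].mean(axis=0) / overall[keep]
        fractions[clu] = mask.mean()
    df = pd.DataFrame(cols, index=norm.gene_ids[keep])
    return SpecificityMatrix(df, pd.Series(fractions))


def shared_feature_genes(
    norm_a: NormMatrix,
    norm_b: NormMatrix | None = None,
    n_top: int = 5000,
    universe_b=None,
) -> list[str]:
    """Shared gene set for a cross-dataset comparison.

    Default: intersection of each dataset's top-n variable genes. When
    the partner is not a single-cell dataset (e.g. a microarray),
    pass its detected-gene universe via `universe_b` instead to
    intersect one top set with a plain gene list.
    """
    top_a = set(select_variable_genes(norm_a, n_top))
    if universe_b is not None:
        other = set(universe_b)
    elif norm_b is not None:
        other = set(select_variable_genes(norm_b, n_top))
    else:
        raise ValueError("provide either norm_b or universe_b")
    shared = sorted(top_a & other)
    if not shared:
        raise ValueError("no shared genes between the datasets")
    return shared


def cross_dataset_correlation(
    spec_a: SpecificityMatrix, spec_b: SpecificityMatrix, shared_genes
) -> pd.DataFrame:
    """Spearman correlation of specificity columns over shared genes.

    Returns a clusters_A × clusters_B matrix; cluster pairs where one
    column is constant (correlation undefined) are reported as NaN with
    a warning. Ties are handled by midranks.
    """
    shared = [g for g in shared_genes]
    missing = [
        g for g in shared if g not in spec_a.values.index or g not in spec_b.values.index
    ]
    if missing:
        raise ValueError(f"shared genes missing from a specificity matrix: {missing[:5]}")
    if len(shared) < 10:
        raise ValueError("need at least 10 shared genes")
    a = spec_a.values.loc[shared]
    b = spec_b.values.loc[shared]
    out = pd.DataFrame(
        np.nan, index=a.columns, columns=b.columns, dtype=float
    )
    for ca in a.columns:
        for cb in b.columns:
            xa, xb = a[ca].to_numpy(), b[cb].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                logger.warning(
                    "constant specificity column (%s, %s); correlation undefined",
                    ca,
                    cb,
                )
                continue
            out.loc[ca, cb] = stats.spearmanr(xa, xb).statistic
    return out


def recovered_correspondence(correlation: pd.DataFrame) -> pd.DataFrame:
    """Per-row argmax of the correspondence matrix: the best-matching
    partner cluster for each cluster of dataset A."""
    best = correlation.idxmax(axis=1)
    return pd.DataFrame(
        {"cluster_a": correlation.index, "cluster_b": best.to_numpy()}
    )
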