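"""Ligand-receptor pair statistics between cell clusters.

For a sender cluster s and receiver cluster r, the score of an ordered
(ligand, receptor) pair is the arithmetic mean of the ligand's mean
expression in s and the receptor's mean expression in r. Significance
of a cluster-pair interaction comes from a permutation null: cluster
labels are shuffled B times and p = (1 + #{permuted score >= observed})
/ (B + 1), so p is never 0 and lies on the grid {1/(B+1), ..., 1}.

Genotype-differential pair expression uses per-cell pair values
((ligand + receptor)/2 on log-normalized expression) compared between
the two groups with a two-sided Wilcoxon test and BH correction;
fold change is computed on de-logged means with pseudocount 1,
consistent with the DE convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import bh_adjust, wilcoxon_rank_sum
from .types import FormatError, LRPairTable, NormMatrix

logger = logging.getLogger("scmosaic")


def standardize_orientation(raw_pairs: pd.DataFrame) -> LRPairTable:
    """Flip receptor-first rows into ligand→receptor order.

    Requires an `orientation` column with values "ligand-receptor" or
    "receptor-ligand"; duplicates arising after flipping are collapsed
    with a warning.
    """
    if "orientation" not in raw_pairs.columns:
        raise FormatError("orientation column required to standardize notation")
    rows = []
    for _, row in raw_pairs.iterrows():
        orient = str(row["orientation"]).strip().lower()
        if orient == "ligand-receptor":
            lig, rec = row["ligand"], row["receptor"]
        elif orient == "receptor-ligand":
            lig, rec = row["receptor"], row["ligand"]
        else:
            raise FormatError(f"unknown orientation value {orient!r}")
        rows.append(
            {"ligand": lig, "receptor": rec, "family": row.get("family", "")}
        )
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["ligand", "receptor"])
    if dup.any():
        logger.warning("%d duplicate pairs collapsed after flipping", int(dup.sum()))
        df = df[~dup]
    return LRPairTable(df.reset_index(drop=True))


def _present_pairs(norm: NormMatrix, pairs: LRPairTable) -> list[tuple[str, str]]:
    universe = set(norm.gene_ids)
    out = []
    for lig, rec in pairs.pairs():
        if lig not in universe or rec not in universe:
            logger.warning("pair (%s, %s) absent from universe; skipped", lig, rec)
            continue
        out.append((lig, rec))
    if not out:
        raise ValueError("no ligand-receptor pair present in the gene universe")
    return out


def _cluster_means(values: np.ndarray, labels: np.ndarray, clusters) -> np.ndarray:
    """clusters × genes matrix of mean expression."""
    return np.vstack([values[labels == c].mean(axis=0) for c in clusters])


def lr_pair_means(
    norm: NormMatrix,
    clusters,
    pairs: LRPairTable,
    min_expr_frac: float = 0.1,
) -> pd.DataFrame:
    """Pair mean expression for every (sender, receiver, pair) triple.

    pair_mean = (mean ligand expression in sender + mean receptor
    expression in receiver) / 2; expressed_flag is False when the
    ligand is expressed in < min_expr_frac of sender cells or the
    receptor in < min_expr_frac of receiver cells.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    labels = pd.Series(clusters)
    labels.index = np.asarray(labels.index, dtype=object)
    labels = labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster label missing for some cells")
    uniq = sorted(labels.unique())
    lab_arr = labels.to_numpy()

    present = _present_pairs(norm, pairs)
    gpos = {g: i for i, g in enumerate(norm.gene_ids)}
    means = _cluster_means(norm.values, lab_arr, uniq)
    fracs = np.vstack(
        [(norm.values[lab_arr == c] > 0).mean(axis=0) for c in uniq]
    )
    cpos = {c: i for i, c in enumerate(uniq)}

    rows = []
    for sender in uniq:
        for receiver in uniq:
            si, ri = cpos[sender], cpos[receiver]
            for lig, rec in present:
                li, reci = gpos[lig], gpos[rec]
                rows.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "ligand": lig,
                        "receptor": rec,
                        "pair_mean": (means[si, li] + means[ri, reci]) / 2.0,
                        "expressed_flag": bool(
                            fracs[si, li] >= min_expr_frac
                            and fracs[ri, reci] >= min_expr_frac
                        ),
                    }
                )
    return pd.DataFrame(rows)


def lr_permutation_test(
    norm: NormMatrix,
    clusters,
    pairs: LRPairTable,
    n_perm: int = 1000,
    seed: int = 0,
    min_expr_frac: float = 0.1,
) -> pd.DataFrame:
    """Cluster-label permutation significance of pair means.

    The null shuffles cluster labels across cells n_perm times; for
    each (sender, receiver, pair), p = (1 + #{permuted pair_mean >=
    observed}) / (n_perm + 1). Non-expressed pairs carry a missing p.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value grid is coarse", n_perm)
    labels = pd.Series(clusters)
    labels.index = np.asarray(labels.index, dtype=object)
    labels = labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster label missing for some cells")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    lab_arr = labels.to_numpy()

    obs = lr_pair_means(norm, clusters, pairs, min_expr_frac)
    present = _present_pairs(norm, pairs)
    gpos = {g: i for i, g in enumerate(norm.gene_ids)}
    genes = sorted({g for pair in present for g in pair})
    sub = norm.values[:, [gpos[g] for g in genes]]
    sub_pos = {g: i for i, g in enumerate(genes)}
    lig_idx = np.array([sub_pos[lig] for lig, _ in present])
    rec_idx = np.array([sub_pos[rec] for _, rec in present])
    cpos = {c: i for i, c in enumerate(uniq)}

    n_c, n_p = len(uniq), len(present)
    obs_mat = np.empty((n_c, n_c, n_p))
    for row in obs.itertuples(index=False):
        pi = present.index((row.ligand, row.receptor))
        obs_mat[cpos[row.sender], cpos[row.receiver], pi] = row.pair_mean

    rng = np.random.default_rng(seed)
    exceed = np.zeros((n_c, n_c, n_p), dtype=np.int64)
    for _ in range(n_perm):
        perm_labels = rng.permutation(lab_arr)
        m = _cluster_means(sub, perm_labels, uniq)  # clusters x genes
        pm = (m[:, None, lig_idx] + m[None, :, rec_idx]) / 2.0
        exceed += pm >= obs_mat - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    out = obs.copy()
    p_col = []
    for row in out.itertuples(index=False):
        pi = present.index((row.ligand, row.receptor))
        p = pvals[cpos[row.sender], cpos[row.receiver], pi]
        p_col.append(p if row.expressed_flag else np.nan)
    out["p_value"] = p_col
    out["n_perm"] = n_perm
    return out


def _cluster_mean_units(values: np.ndarray, clusters, cell_ids) -> np.ndarray:
    labels = pd.Series(clusters)
    labels.index = np.asarray(labels.index, dtype=object)
    labels = labels.reindex(cell_ids)
    if labels.isna().any():
        raise ValueError("cluster label missing for some cells")
    lab = labels.to_numpy()
    return np.array([values[lab == c].mean() for c in sorted(set(lab))])


def lr_differential(
    norm_a: NormMatrix,
    norm_b: NormMatrix,
    pairs: LRPairTable,
    unit: str = "cell",
    clusters_a=None,
    clusters_b=None,
) -> pd.DataFrame:
    """Differential pair expression between two cell groups.

    Per cell, pair expression = (ligand + receptor)/2 on log-normalized
    values; a two-sided Wilcoxon compares the per-cell values between
    the groups, with BH over pairs. log2FC is computed on de-logged
    group means with pseudocount 1 (group A over group B).

    With unit="cluster" (cluster labels required for both groups) the
    Wilcoxon observations are per-cluster mean pair values instead of
    per-cell values — a coarser reading with clusters as the unit of
    evidence. log2FC is computed on cells either way.
    """
    if norm_a.n_cells < 3 or norm_b.n_cells < 3:
        raise ValueError("each group needs at least 3 cells")
    if unit not in ("cell", "cluster"):
        raise ValueError(f"unknown unit {unit!r}")
    if unit == "cluster" and (clusters_a is None or clusters_b is None):
        raise ValueError("unit='cluster' requires cluster labels for both groups")
    rows = []
    set_a, set_b = set(norm_a.gene_ids), set(norm_b.gene_ids)
    for lig, rec in pairs.pairs():
        if not {lig, rec} <= set_a or not {lig, rec} <= set_b:
            logger.warning("pair (%s, %s) missing from a group; skipped", lig, rec)
            continue
        va = (norm_a.gene_vector(lig) + norm_a.gene_vector(rec)) / 2.0
        vb = (norm_b.gene_vector(lig) + norm_b.gene_vector(rec)) / 2.0
        lfc = np.log2(
            (np.expm1(va).mean() + 1.0) / (np.expm1(vb).mean() + 1.0)
        )
        if unit == "cluster":
            ua = _cluster_mean_units(va, clusters_a, norm_a.cell_ids)
            ub = _cluster_mean_units(vb, clusters_b, norm_b.cell_ids)
        else:
            ua, ub = va, vb
        rows.append(
            {
                "ligand": lig,
                "receptor": rec,
                "log2_fold_change": lfc,
                "p_value": wilcoxon_rank_sum(ua, ub),
            }
        )
    if not rows:
        raise ValueError("no testable pairs")
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
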