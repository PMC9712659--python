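"""Binned pseudotime expression profiles and cosine-similarity tests.

Pseudotime is a supplied per-cell scalar (inferred upstream); this
module bins a gene's log-normalized expression into equal-width bins
over the pseudotime range, compares two binned profiles with cosine
similarity, and derives a permutation p-value by shuffling the bin
order of one profile: p = (1 + #{|cos_perm| >= |cos_obs|}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import NormMatrix


@dataclass
class TrajectoryProfile:
    """Mean expression of one gene per pseudotime bin."""

    gene: str
    n_bins: int
    bin_means: np.ndarray  # NaN for empty bins
    bin_counts: np.ndarray
    bin_edges: np.ndarray


@dataclass
class SimilarityResult:
    cosine: float
    p_value: float
    n_perm: int
    seed: int
    n_bins_used: int


def bin_profile(
    norm: NormMatrix, pseudotime, gene: str, n_bins: int = 20
) -> TrajectoryProfile:
    """Equal-width binned mean expression of `gene` along pseudotime.

    Bins partition [min(t), max(t)]; empty bins carry NaN and are
    excluded pairwise downstream.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t = pd.Series(pseudotime)
    t.index = np.asarray(t.index, dtype=object)
    t = t.reindex(norm.cell_ids)
    if t.isna().any():
        raise ValueError("pseudotime missing for some cells")
    tv = t.to_numpy(dtype=float)
    expr = norm.gene_vector(gene)
    edges = np.linspace(tv.min(), tv.max(), n_bins + 1)
    # right-inclusive last bin so max(t) lands in bin n_bins - 1
    idx = np.clip(np.digitize(tv, edges[1:-1]), 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            means[b] = expr[mask].mean()
    if (counts > 0).sum() < 2:
        raise ValueError("all cells fall in one bin; use fewer bins")
    return TrajectoryProfile(gene, n_bins, means, counts, edges)


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (‖u‖ ‖v‖) after pairwise removal of missing bins;
    NaN when either vector has zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must share the bin grid")
    ok = ~(np.isnan(u) | np.isnan(v))
    u, v = u[ok], v[ok]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.dot(u, v) / (nu * nv))


def cosine_perm_test(
    profile_a: TrajectoryProfile,
    profile_b: TrajectoryProfile,
    n_perm: int = 1000,
    seed: int = 0,
) -> SimilarityResult:
    """Two-sided permutation test on |cosine| between two profiles.

    The bin order of profile_b is shuffled n_perm times;
    p = (1 + #{|cos_perm| >= |cos_obs|}) / (n_perm + 1), never 0 and
    reproducible for a fixed seed.
    """
    if profile_a.n_bins != profile_b.n_bins:
        raise ValueError("profiles must share the bin grid")
    u = np.asarray(profile_a.bin_means, dtype=float)
    v = np.asarray(profile_b.bin_means, dtype=float)
    ok = ~(np.isnan(u) | np.isnan(v))
    if int(ok.sum()) < 4:
        raise ValueError("fewer than 4 usable bins; permutation space too small")
    u, v = u[ok], v[ok]
    obs = cosine_similarity(u, v)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        c = cosine_similarity(u, rng.permutation(v))
        if abs(c) >= abs(obs) - 1e-12:
            exceed += 1
    return SimilarityResult(
        cosine=obs,
        p_value=(1.0 + exceed) / (n_perm + 1.0),
        n_perm=n_perm,
        seed=seed,
        n_bins_used=int(ok.sum()),
    )
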