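"""Synthetic single-cell data with planted ground truth.

Counts are negative-binomial with a shared dispersion across genes.
The per-gene, per-cell mean is a product of independent factors:

    mu[c, g] = base_mean[g] * cluster_fold * genotype_fold
               * regulon_fold * exp(amplitude * direction * t_c)
               * library_size[c]

so every downstream statistic (cluster markers, genotype DE, regulon
programs, ligand-receptor co-expression, pseudotime ramps) has a known
planted truth. Doublets are sums of two random cells and carry a
simulated doublet score above 0.5; singlets score below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CountMatrix, ConfigError, Regulon, make_cell_meta


@dataclass
class RegulonSpec:
    """A planted regulon program: fold applied to the targets in cells
    matching the cluster/genotype filters (None = all)."""

    regulon: Regulon
    fold: float = 1.0
    clusters: tuple[str, ...] | None = None
    genotypes: tuple[str, ...] | None = None


@dataclass
class LRSpec:
    """A planted ligand-receptor axis: ligand boosted in the sender
    cluster, receptor in the receiver cluster."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    fold: float = 8.0


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    cell_counts maps (cluster, genotype, treatment) to a cell count.
    Folds are multiplicative effects on the negative-binomial mean;
    nb_dispersion is the shared NB size parameter (variance =
    mu + mu^2 / dispersion). gene_mean_sigma spreads per-gene baseline
    means log-normally around baseline_mean (0 = identical baselines).
    """

    cell_counts: dict[tuple[str, str, str], int]
    n_genes: int = 2000
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.5
    gene_mean_sigma: float = 0.0
    library_sigma: float = 0.3
    cluster_markers: list[tuple[str, str, float]] = field(default_factory=list)
    genotype_markers: list[tuple[str, str, float]] = field(default_factory=list)
    regulon_specs: list[RegulonSpec] = field(default_factory=list)
    lr_specs: list[LRSpec] = field(default_factory=list)
    pseudotime_genes: list[tuple[str, int, float]] = field(default_factory=list)
    pseudotime_clusters: tuple[str, ...] | None = None
    doublet_fraction: float = 0.0
    n_mito_genes: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.doublet_fraction < 1):
            raise ConfigError("doublet_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigError("dispersion and baseline mean must be positive")
        for _, _, f in self.cluster_markers + self.genotype_markers:
            if f <= 0:
                raise ConfigError("fold changes must be > 0")
        for spec in self.regulon_specs:
            if spec.fold <= 0:
                raise ConfigError("regulon fold must be > 0")
        for spec in self.lr_specs:
            if spec.fold <= 0:
                raise ConfigError("L-R fold must be > 0")

    @property
    def clusters(self) -> list[str]:
        return sorted({k[0] for k in self.cell_counts})


@dataclass
class GroundTruth:
    """Planted truth tables aligned with a simulated dataset."""

    gene_base_means: pd.Series
    cluster_markers: pd.DataFrame  # gene, cluster, fold
    genotype_de: pd.DataFrame  # gene, genotype, fold
    regulons: pd.DataFrame  # tf, size, fold, clusters, genotypes, differential
    lr_pairs: pd.DataFrame  # ligand, receptor, sender, receiver, fold
    doublets: pd.Series  # bool per cell_id
    pseudotime_genes: pd.DataFrame  # gene, direction, amplitude


def gene_universe(config: SimConfig) -> np.ndarray:
    """Gene symbols: marker/regulon/LR genes first, mt- genes last,
    filler genes in between."""
    named: list[str] = []
    for g, _, _ in config.cluster_markers + config.genotype_markers:
        named.append(g)
    for spec in config.regulon_specs:
        named.append(spec.regulon.tf)
        named.extend(spec.regulon.targets)
    for spec in config.lr_specs:
        named.extend([spec.ligand, spec.receptor])
    for g, _, _ in config.pseudotime_genes:
        named.append(g)
    named = list(dict.fromkeys(named))
    mito = [f"mt-Sim{i}" for i in range(1, config.n_mito_genes + 1)]
    n_filler = config.n_genes - len(named) - len(mito)
    if n_filler < 0:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for {len(named)} named genes "
            f"and {len(mito)} mitochondrial genes"
        )
    filler = [f"Gene{i:05d}" for i in range(1, n_filler + 1)]
    return np.array(named + filler + mito, dtype=object)


def _mean_matrix(config: SimConfig, cells: pd.DataFrame, genes: np.ndarray, rng):
    gpos = {g: i for i, g in enumerate(genes)}
    base = config.baseline_mean * np.exp(
        rng.normal(0.0, config.gene_mean_sigma, size=len(genes))
        - config.gene_mean_sigma**2 / 2.0
    )
    mu = np.tile(base, (len(cells), 1))

    cluster = cells["cluster"].to_numpy()
    genotype = cells["genotype"].to_numpy()
    for gene, clu, fold in config.cluster_markers:
        if gene not in gpos:
            raise ConfigError(f"marker gene {gene!r} absent from gene universe")
        mu[cluster == clu, gpos[gene]] *= fold
    for gene, gt, fold in config.genotype_markers:
        if gene not in gpos:
            raise ConfigError(f"marker gene {gene!r} absent from gene universe")
        mu[genotype == gt, gpos[gene]] *= fold
    for spec in config.regulon_specs:
        mask = np.ones(len(cells), dtype=bool)
        if spec.clusters is not None:
            mask &= np.isin(cluster, spec.clusters)
        if spec.genotypes is not None:
            mask &= np.isin(genotype, spec.genotypes)
        cols = [gpos[t] for t in spec.regulon.targets if t in gpos]
        if not cols:
            raise ConfigError(f"regulon {spec.regulon.tf!r} has no genes in universe")
        mu[np.ix_(mask, cols)] *= spec.fold
    for spec in config.lr_specs:
        for gene, clu in ((spec.ligand, spec.sender), (spec.receptor, spec.receiver)):
            if gene not in gpos:
                raise ConfigError(f"L-R gene {gene!r} absent from gene universe")
            mu[cluster == clu, gpos[gene]] *= spec.fold

    pt = cells["pseudotime"].to_numpy(dtype=float)
    has_pt = ~np.isnan(pt)
    for gene, direction, amplitude in config.pseudotime_genes:
        if gene not in gpos:
            raise ConfigError(f"pseudotime gene {gene!r} absent from gene universe")
        mu[has_pt, gpos[gene]] *= np.exp(amplitude * direction * pt[has_pt])
    return mu, base


def _sample_nb(mu: np.ndarray, dispersion: float, rng) -> np.ndarray:
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_dataset(config: SimConfig):
    """Draw one dataset: (CountMatrix, CellMeta DataFrame, GroundTruth).

    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config)

    rows = []
    i = 0
    for (clu, gt, tr), n in sorted(config.cell_counts.items()):
        for _ in range(n):
            rows.append((f"cell{i:05d}", clu, gt, tr))
            i += 1
    cells = pd.DataFrame(rows, columns=["cell_id", "cluster", "genotype", "treatment"])

    pt_clusters = config.pseudotime_clusters
    if pt_clusters is None and config.pseudotime_genes:
        pt_clusters = tuple(config.clusters)
    pt = np.full(len(cells), np.nan)
    if pt_clusters:
        mask = cells["cluster"].isin(pt_clusters).to_numpy()
        pt[mask] = rng.uniform(0.0, 1.0, size=int(mask.sum()))
    cells["pseudotime"] = pt

    mu, base_means = _mean_matrix(config, cells, genes, rng)
    libsize = np.exp(
        rng.normal(0.0, config.library_sigma, size=len(cells))
        - config.library_sigma**2 / 2.0
    )
    counts = _sample_nb(mu * libsize[:, None], config.nb_dispersion, rng)

    n_cells = len(cells)
    n_doublets = int(round(config.doublet_fraction * n_cells))
    is_doublet = np.zeros(n_cells, dtype=bool)
    if n_doublets:
        dbl_idx = rng.choice(n_cells, size=n_doublets, replace=False)
        partners = rng.integers(0, n_cells, size=n_doublets)
        counts[dbl_idx] = counts[dbl_idx] + counts[partners]
        is_doublet[dbl_idx] = True
    score = rng.uniform(0.0, 0.499, size=n_cells)
    score[is_doublet] = rng.uniform(0.501, 1.0, size=n_doublets)
    cells["doublet_score"] = score

    truth = GroundTruth(
        gene_base_means=pd.Series(base_means, index=genes, dtype=float),
        cluster_markers=pd.DataFrame(
            config.cluster_markers, columns=["gene", "cluster", "fold"]
        ),
        genotype_de=pd.DataFrame(
            config.genotype_markers, columns=["gene", "genotype", "fold"]
        ),
        regulons=pd.DataFrame(
            [
                {
                    "tf": s.regulon.tf,
                    "size": s.regulon.size,
                    "fold": s.fold,
                    "clusters": s.clusters,
                    "genotypes": s.genotypes,
                    "differential": s.fold != 1.0 and s.genotypes is not None,
                }
                for s in config.regulon_specs
            ]
        ),
        lr_pairs=pd.DataFrame(
            [
                {
                    "ligand": s.ligand,
                    "receptor": s.receptor,
                    "sender": s.sender,
                    "receiver": s.receiver,
                    "fold": s.fold,
                }
                for s in config.lr_specs
            ]
        ),
        doublets=pd.Series(is_doublet, index=cells["cell_id"].to_numpy()),
        pseudotime_genes=pd.DataFrame(
            config.pseudotime_genes, columns=["gene", "direction", "amplitude"]
        ),
    )

    matrix = CountMatrix(counts, cells["cell_id"].to_numpy(), genes)
    return matrix, make_cell_meta(cells), truth


def simulate_paired_datasets(config: SimConfig, n_shared_clusters: int, seed: int):
    """Two datasets sharing marker programs for corresponding clusters.

    Dataset A uses clusters sharedA0..; dataset B relabels them with a
    seeded permutation so the correspondence is non-trivial. Noise is
    independent between the datasets. Returns
    ((countsA, metaA), (countsB, metaB), correspondence DataFrame).
    """
    if n_shared_clusters < 2:
        raise ConfigError("need at least 2 shared clusters")
    rng = np.random.default_rng(seed)
    clusters_a = [f"sharedA{i}" for i in range(n_shared_clusters)]
    perm = rng.permutation(n_shared_clusters)
    clusters_b = [f"sharedB{perm[i]}" for i in range(n_shared_clusters)]

    n_per = next(iter(config.cell_counts.values())) if config.cell_counts else 200
    genotypes = sorted({k[1] for k in config.cell_counts}) or ["WT"]
    treatments = sorted({k[2] for k in config.cell_counts}) or ["none"]
    gt, tr = genotypes[0], treatments[0]

    # one shared marker program: a block of genes per corresponding cluster,
    # sized like a typical cell-type signature
    markers_per = 25
    marker_fold = 8.0
    markers_a, markers_b = [], []
    for i in range(n_shared_clusters):
        for j in range(markers_per):
            g = f"Shared{i}_{j}"
            markers_a.append((g, clusters_a[i], marker_fold))
            markers_b.append((g, clusters_b[i], marker_fold))

    base = replace(
        config,
        cluster_markers=[],
        genotype_markers=[],
        regulon_specs=[],
        lr_specs=[],
        pseudotime_genes=[],
        doublet_fraction=0.0,
    )
    cfg_a = replace(
        base,
        cell_counts={(c, gt, tr): n_per for c in clusters_a},
        cluster_markers=markers_a,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cfg_b = replace(
        base,
        cell_counts={(c, gt, tr): n_per for c in clusters_b},
        cluster_markers=markers_b,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    counts_a, meta_a, _ = simulate_dataset(cfg_a)
    counts_b, meta_b, _ = simulate_dataset(cfg_b)
    correspondence = pd.DataFrame(
        {"cluster_a": clusters_a, "cluster_b": clusters_b}
    )
    return (counts_a, meta_a), (counts_b, meta_b), correspondence


def default_config(seed: int = 0) -> SimConfig:
    """Reference synthetic study: 5 macrophage-like clusters, two
    genotypes under treatment, planted markers, one genotype-responsive
    regulon program, a chemokine sender→receiver axis, and a pseudotime
    ramp in two clusters."""
    clusters = ["C0", "C1", "C2", "C3", "C4"]
    counts = {}
    for c in clusters:
        for gt in ("WT", "Mut"):
            counts[(c, gt, "AngII")] = 120

    markers = []
    for ci, c in enumerate(clusters):
        for j in range(6):
            markers.append((f"Mk{ci}_{j}", c, 8.0))

    genotype_markers = [(f"DeG{j:02d}", "Mut", 4.0) for j in range(20)]

    reg_active = Regulon("Irf7sim", [f"RegT{j:02d}" for j in range(25)])
    reg_null = Regulon("Nullsim", [f"NulT{j:02d}" for j in range(25)])
    regulon_specs = [
        RegulonSpec(reg_active, fold=4.0, genotypes=("WT",)),
        RegulonSpec(reg_null, fold=1.0),
    ]

    lr_specs = [LRSpec("Ccl5", "Ccr5", sender="C4", receiver="C2", fold=10.0)]

    pt_genes = [("Ccr2", +1, 2.0), ("Cd72", +1, 2.0), ("PtDown", -1, 2.0)]

    return SimConfig(
        cell_counts=counts,
        n_genes=2000,
        nb_dispersion=2.0,
        baseline_mean=0.5,
        gene_mean_sigma=0.0,
        library_sigma=0.3,
        cluster_markers=markers,
        genotype_markers=genotype_markers,
        regulon_specs=regulon_specs,
        lr_specs=lr_specs,
        pseudotime_genes=pt_genes,
        pseudotime_clusters=("C2", "C4"),
        doublet_fraction=0.05,
        n_mito_genes=5,
        seed=seed,
    )
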