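"""In-memory domain types shared by every analysis stage.

Matrices are dense or sparse cells × genes arrays wrapped with their
row (cell) and column (gene) identifiers; metadata and result tables
are pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """An on-disk file violates its format contract."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


def _as_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


def _check_ids(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Cells × genes matrix of non-negative integer UMI counts."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        self.values = _as_dense(self.values)
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if (self.values < 0).any():
            raise FormatError("counts must be non-negative")
        if not np.allclose(self.values, np.round(self.values)):
            raise FormatError("counts must be integers")
        self.values = self.values.astype(np.int64, copy=False)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = _resolve_index(mask_or_ids, self.cell_ids)
        return CountMatrix(self.values[idx], self.cell_ids[idx], self.gene_ids)

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = _resolve_index(mask_or_ids, self.gene_ids)
        return CountMatrix(self.values[:, idx], self.cell_ids, self.gene_ids[idx])

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if len(hits) == 0:
            raise KeyError(f"gene {gene!r} not present")
        return int(hits[0])


def _resolve_index(mask_or_ids, ids: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if len(arr) != len(ids):
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    pos = {v: i for i, v in enumerate(ids)}
    try:
        return np.array([pos[v] for v in arr], dtype=int)
    except KeyError as e:
        raise KeyError(f"identifier {e.args[0]!r} not present") from None


@dataclass
class NormMatrix:
    """Cells × genes log-normalized expression, ln(1 + count/total * scale)."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scale_factor: float = 10_000.0

    def __post_init__(self):
        self.values = _as_dense(self.values).astype(float)
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("normalized matrix shape mismatch")
        if (self.values < 0).any():
            raise FormatError("log-normalized values must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_cells(self, mask_or_ids) -> "NormMatrix":
        idx = _resolve_index(mask_or_ids, self.cell_ids)
        return NormMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_ids, self.scale_factor
        )

    def subset_genes(self, mask_or_ids) -> "NormMatrix":
        idx = _resolve_index(mask_or_ids, self.gene_ids)
        return NormMatrix(
            self.values[:, idx], self.cell_ids, self.gene_ids[idx], self.scale_factor
        )

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if len(hits) == 0:
            raise KeyError(f"gene {gene!r} not present")
        return int(hits[0])

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]


@dataclass
class ScaledMatrix:
    """Per-gene standardized (z-scored) expression, clipped to ±clip_max."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    clip_max: float = 10.0

    def __post_init__(self):
        self.values = _as_dense(self.values).astype(float)
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("scaled matrix shape mismatch")
        if np.abs(self.values).max(initial=0.0) > self.clip_max + 1e-9:
            raise FormatError("scaled values exceed clip_max")

    def gene_vector(self, gene: str) -> np.ndarray:
        hits = np.flatnonzero(self.gene_ids == gene)
        if len(hits) == 0:
            raise KeyError(f"gene {gene!r} not present")
        return self.values[:, int(hits[0])]


# Required per-cell metadata columns; pseudotime and doublet_score optional.
CELLMETA_REQUIRED = ("cell_id", "cluster", "genotype", "treatment")


def make_cell_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell metadata table (CellMeta contract).

    One row per cell_id; cluster/genotype/treatment non-empty for every
    cell; doublet_score, when present, in [0, 1].
    """
    missing = [c for c in CELLMETA_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"cell metadata missing columns: {missing}")
    if df["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id in metadata")
    for col in ("cluster", "genotype", "treatment"):
        vals = df[col].astype(str)
        if (vals.str.len() == 0).any() or df[col].isna().any():
            raise FormatError(f"empty values in required column {col!r}")
    if "doublet_score" in df.columns:
        ds = df["doublet_score"].dropna()
        if ((ds < 0) | (ds > 1)).any():
            raise FormatError("doublet_score outside [0, 1]")
    if "pseudotime" in df.columns:
        pt = df["pseudotime"].dropna()
        if (pt < 0).any():
            raise FormatError("pseudotime must be non-negative")
    return df.reset_index(drop=True)


@dataclass
class GeneSet:
    """A named, duplicate-free gene list."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Regulon:
    """A transcription factor with its inferred target genes."""

    tf: str
    targets: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.tf:
            raise FormatError("regulon must name a transcription factor")
        if len(set(self.targets)) != len(self.targets):
            raise FormatError(f"regulon {self.tf!r} has duplicate targets")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class LRPairTable:
    """Ordered ligand→receptor pairs, optionally tagged with a family."""

    table: pd.DataFrame  # columns: ligand, receptor, family

    def __post_init__(self):
        for col in ("ligand", "receptor"):
            if col not in self.table.columns:
                raise FormatError(f"L-R table missing column {col!r}")
        if "family" not in self.table.columns:
            self.table = self.table.assign(family="")
        if self.table.duplicated(subset=["ligand", "receptor"]).any():
            raise FormatError("duplicate (ligand, receptor) rows")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def filter_families(self, prefixes=("Ccl", "Ccr", "Cx")) -> "LRPairTable":
        """Keep pairs whose ligand or receptor matches a family prefix.

        The chemokine restriction keeps CCL-/CCR-/CX- family pairs;
        matching is case-insensitive on the gene-symbol prefix.
        """
        pref = tuple(p.lower() for p in prefixes)

        def _chemokine(row) -> bool:
            return str(row["ligand"]).lower().startswith(pref) or str(
                row["receptor"]
            ).lower().startswith(pref)

        keep = self.table.apply(_chemokine, axis=1)
        return LRPairTable(self.table[keep].reset_index(drop=True))

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["ligand"], self.table["receptor"]))


@dataclass
class OrthologMap:
    """Explicit source→target gene-symbol renaming table."""

    table: pd.DataFrame  # columns: source_symbol, target_symbol
    allow_many_to_many: bool = False

    def __post_init__(self):
        for col in ("source_symbol", "target_symbol"):
            if col not in self.table.columns:
                raise FormatError(f"ortholog map missing column {col!r}")
        if not self.allow_many_to_many and self.table["source_symbol"].duplicated().any():
            raise FormatError(
                "duplicate source symbols; pass allow_many_to_many=True to permit"
            )

    def apply(self, genes) -> list[str]:
        mapping = dict(
            zip(self.table["source_symbol"], self.table["target_symbol"])
        )
        return [mapping.get(g, g) for g in genes]
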