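"""Readers and writers for the on-disk formats.

Counts travel as MatrixMarket coordinate files with features/barcodes
sidecars (the common 10x-style triplet, genes in rows); metadata and
result tables as TSV with a header row; gene sets as GMT; regulons as
long-format (tf, target) TSV. Everything downstream consumes only the
in-memory domain types.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    CountMatrix,
    FormatError,
    GeneSet,
    LRPairTable,
    OrthologMap,
    Regulon,
    make_cell_meta,
)

logger = logging.getLogger("scmosaic")


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr; level settable from the CLI."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _feature_symbols(lines: list[str]) -> list[str]:
    """Resolve feature sidecar lines to unique gene symbols.

    Two-column (id<TAB>symbol) files use the symbol column; duplicate
    symbols are disambiguated with ".1", ".2", ... suffixes.
    """
    symbols = []
    for line in lines:
        fields = line.split("\t")
        symbols.append(fields[1] if len(fields) >= 2 else fields[0])
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read an MTX counts triplet into a cells × genes CountMatrix.

    The matrix file may be features × barcodes (10x convention) or
    barcodes × features; orientation is resolved against the sidecar
    lengths, preferring features-in-rows when square.
    """
    barcodes = _read_lines(barcodes_path)
    features = _feature_symbols(_read_lines(features_path))
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as e:
        raise FormatError(f"cannot parse MatrixMarket file: {e}") from None
    mat = sp.coo_matrix(mat)
    if not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("matrix contains non-integer values")
    n_feat, n_bc = len(features), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        mat = mat.T
    elif mat.shape == (n_bc, n_feat):
        pass
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_feat} features x "
            f"{n_bc} barcodes nor its transpose"
        )
    return CountMatrix(mat.tocsr().toarray(), np.array(barcodes), np.array(features))


def write_counts_mtx(counts: CountMatrix, out_dir, prefix: str = "") -> None:
    """Write a CountMatrix as matrix.mtx + features.tsv + barcodes.tsv.

    Stored features × barcodes (genes in rows), integer coordinate
    format; round-trips bit-exactly through :func:`read_counts_mtx`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.values.T.astype(np.int64))
    scipy.io.mmwrite(str(out / f"{prefix}matrix.mtx"), mat, field="integer")
    (out / f"{prefix}features.tsv").write_text(
        "".join(f"{g}\n" for g in counts.gene_ids)
    )
    (out / f"{prefix}barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in counts.cell_ids)
    )


def read_gene_sets_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then tab-separated genes.

    Descriptions are discarded; duplicate genes within a line are
    dropped with a logged warning.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "gene set %r (line %d): %d duplicate genes dropped",
                    name,
                    lineno,
                    len(genes) - len(unique),
                )
            sets.append(GeneSet(name, unique))
    return sets


def write_gene_sets_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def read_lr_pairs(path, chemokine_only: bool = False) -> LRPairTable:
    """Read a ligand/receptor pair TSV.

    Requires `ligand` and `receptor` columns; an optional `orientation`
    column with value "receptor-ligand" marks rows to flip into
    ligand→receptor order. Duplicates (after flipping) are collapsed
    with a warning. With chemokine_only, restrict to CCL-/CCR-/CX-
    family pairs.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"L-R table {path} missing required column {col!r}")
    if "orientation" in df.columns:
        from .interactions import standardize_orientation

        table = standardize_orientation(df)
    else:
        dup = df.duplicated(subset=["ligand", "receptor"])
        if dup.any():
            logger.warning("%d duplicate L-R rows collapsed", int(dup.sum()))
            df = df[~dup]
        table = LRPairTable(df.reset_index(drop=True))
    if chemokine_only:
        table = table.filter_families()
    return table


def read_regulons_tsv(path) -> list[Regulon]:
    """Read long-format (tf, target) regulon TSV into Regulon objects."""
    df = pd.read_csv(path, sep="\t")
    for col in ("tf", "target"):
        if col not in df.columns:
            raise FormatError(f"regulon table {path} missing column {col!r}")
    regulons = []
    for tf, grp in df.groupby("tf", sort=True):
        targets = list(dict.fromkeys(grp["target"]))
        if len(targets) != len(grp):
            logger.warning("regulon %r: duplicate targets dropped", tf)
        regulons.append(Regulon(str(tf), [str(t) for t in targets]))
    return regulons


def write_regulons_tsv(regulons: list[Regulon], path) -> None:
    rows = [(r.tf, t) for r in regulons for t in r.targets]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_cell_meta(path) -> pd.DataFrame:
    return make_cell_meta(pd.read_csv(path, sep="\t"))


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path, allow_many_to_many: bool = False) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    return OrthologMap(df, allow_many_to_many=allow_many_to_many)


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a results TSV with header; optional leading comment line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
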