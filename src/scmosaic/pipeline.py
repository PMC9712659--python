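"""End-to-end orchestration from a single YAML config.

Stages run in a fixed order — qc → markers/DE → specificity → regulons
→ ligand-receptor → trajectory — and every table lands on disk as TSV
with a parameter-hash header comment. A manifest (JSON) records
parameters, seeds and entity counts at each filter so a rerun with the
same config is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .differential import find_all_markers, wilcoxon_de
from .interactions import lr_differential, lr_permutation_test
from .preprocess import qc_pipeline, select_variable_genes
from .regulons import differential_regulons, module_scores, regulon_activity
from .simulate import SimConfig, default_config, simulate_dataset
from .specificity import specificity_matrix
from .trajectory import bin_profile, cosine_perm_test
from .types import ConfigError

logger = logging.getLogger("scmosaic")

DEFAULTS = {
    "qc": {
        "min_cells": 10,
        "lower_pct": 10.0,
        "upper_pct": 90.0,
        "doublet_threshold": 0.5,
        "mito_prefix": "mt-",
        "scale_factor": 10_000.0,
        "cell_filter_mode": "union",
    },
    "markers": {"min_pct": 0.25, "logfc_threshold": 0.25},
    "de": {"group_by": "genotype", "contrast": None, "min_pct": 0.1,
           "logfc_threshold": 0.0, "fdr": 0.05},
    "specificity": {"enabled": True},
    "regulons": {"path": None, "top_fraction": 0.05, "n_bins": 24,
                 "n_ctrl": 100, "seed": None, "alpha": 0.05,
                 "min_deg_fraction": 0.05},
    "lr": {"path": None, "chemokine_only": True, "n_perm": 1000,
           "seed": None, "min_expr_frac": 0.1},
    "trajectory": {"genes": [], "n_bins": 20, "n_perm": 1000, "seed": None},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {}
    for stage, defaults in DEFAULTS.items():
        block = dict(defaults)
        block.update(user.get(stage, {}) or {})
        cfg[stage] = block
    cfg["inputs"] = user.get("inputs", {})
    cfg["seed"] = user.get("seed")
    if cfg["seed"] is None:
        raise ConfigError("config must set a top-level seed")
    for stage in ("regulons", "lr", "trajectory"):
        if cfg[stage]["seed"] is None:
            cfg[stage]["seed"] = cfg["seed"]
    return cfg


def _param_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run every enabled stage; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = _param_hash(cfg)
    manifest: dict = {"parameters": cfg, "param_hash": phash, "counts": {}}

    inputs = cfg["inputs"]
    if inputs.get("matrix"):
        counts = sio.read_counts_mtx(
            inputs["matrix"], inputs["features"], inputs["barcodes"]
        )
        meta = sio.read_cell_meta(inputs["meta"])
    else:
        logger.info("no input matrix configured; simulating the demo dataset")
        counts, meta, _ = simulate_dataset(default_config(cfg["seed"]))

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("qc")
        norm, meta, qc_log = qc_pipeline(counts, meta, **cfg["qc"])
        manifest["counts"].update(qc_log)

        stage("markers")
        clusters = meta.set_index("cell_id")["cluster"]
        markers = find_all_markers(norm, clusters, **cfg["markers"])
        sio.write_table(markers, out / "markers.tsv", f"param_hash={phash}")
        manifest["counts"]["marker_rows"] = len(markers)

        de_cfg = dict(cfg["de"])
        fdr = de_cfg.pop("fdr")
        group_col = de_cfg.pop("group_by")
        contrast = de_cfg.pop("contrast")
        groups = meta.set_index("cell_id")[group_col]
        if contrast is None:
            contrast = sorted(groups.unique())[:2]
        stage("de")
        g1 = groups.index[groups == contrast[0]].to_numpy()
        g2 = groups.index[groups == contrast[1]].to_numpy()
        de = wilcoxon_de(norm, g1, g2, **de_cfg)
        sio.write_table(de, out / "de.tsv", f"param_hash={phash}")
        manifest["counts"]["de_tested"] = len(de)
        manifest["counts"]["de_significant"] = int((de["p_adjusted"] < fdr).sum())

        if cfg["specificity"]["enabled"]:
            stage("specificity")
            spec = specificity_matrix(norm, clusters)
            sio.write_table(
                spec.values.reset_index(names="gene"),
                out / "specificity.tsv",
                f"param_hash={phash}",
            )
            manifest["counts"]["specificity_genes"] = len(spec.values)

        reg_cfg = cfg["regulons"]
        if reg_cfg.get("path"):
            stage("regulons")
            regs = sio.read_regulons_tsv(reg_cfg["path"])
            act = regulon_activity(
                norm, regs, reg_cfg["top_fraction"], reg_cfg["seed"]
            )
            sio.write_table(
                act.scores.reset_index(names="cell_id"),
                out / "regulon_auc.tsv",
                f"param_hash={phash}",
            )
            ms = module_scores(
                norm, regs, reg_cfg["n_bins"], reg_cfg["n_ctrl"], reg_cfg["seed"]
            )
            ledger = differential_regulons(
                ms, groups.loc[list(ms.scores.index)], de, regs,
                reg_cfg["alpha"], reg_cfg["min_deg_fraction"],
            )
            sio.write_table(ledger, out / "regulon_ledger.tsv", f"param_hash={phash}")
            manifest["counts"]["regulons_tested"] = len(ledger)
            manifest["counts"]["regulons_passing"] = int(ledger["pass_flag"].sum())

        lr_cfg = cfg["lr"]
        if lr_cfg.get("path"):
            stage("lr")
            pairs = sio.read_lr_pairs(
                lr_cfg["path"], chemokine_only=lr_cfg["chemokine_only"]
            )
            inter = lr_permutation_test(
                norm, clusters, pairs, lr_cfg["n_perm"], lr_cfg["seed"],
                lr_cfg["min_expr_frac"],
            )
            sio.write_table(inter, out / "lr_interactions.tsv", f"param_hash={phash}")
            norm_a = norm.subset_cells(g1)
            norm_b = norm.subset_cells(g2)
            diff = lr_differential(norm_a, norm_b, pairs)
            sio.write_table(diff, out / "lr_differential.tsv", f"param_hash={phash}")
            manifest["counts"]["lr_rows"] = len(inter)

        tr_cfg = cfg["trajectory"]
        if tr_cfg.get("genes"):
            stage("trajectory")
            pt_meta = meta.dropna(subset=["pseudotime"])
            pt = pt_meta.set_index("cell_id")["pseudotime"]
            sub = norm.subset_cells(pt.index.to_numpy())
            profiles = {
                g: bin_profile(sub, pt, g, tr_cfg["n_bins"])
                for g in tr_cfg["genes"]
            }
            rows = []
            gene_list = list(tr_cfg["genes"])
            for i in range(len(gene_list)):
                for j in range(i + 1, len(gene_list)):
                    res = cosine_perm_test(
                        profiles[gene_list[i]], profiles[gene_list[j]],
                        tr_cfg["n_perm"], tr_cfg["seed"],
                    )
                    rows.append(
                        {
                            "gene_a": gene_list[i],
                            "gene_b": gene_list[j],
                            "cosine": res.cosine,
                            "p_value": res.p_value,
                            "n_perm": res.n_perm,
                        }
                    )
            sio.write_table(
                pd.DataFrame(rows), out / "trajectory_similarity.tsv",
                f"param_hash={phash}",
            )
            manifest["counts"]["trajectory_pairs"] = len(rows)

        manifest["counts"]["variable_genes"] = len(
            select_variable_genes(norm, min(5000, norm.n_genes))
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return manifest


def write_demo_inputs(out_dir, seed: int = 0) -> SimConfig:
    """Materialize the demo synthetic dataset (MTX + TSV + regulons +
    L-R pairs + truth tables) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed)
    counts, meta, truth = simulate_dataset(cfg)
    sio.write_counts_mtx(counts, out)
    sio.write_cell_meta(meta, out / "meta.tsv")
    regs = [s.regulon for s in cfg.regulon_specs]
    sio.write_regulons_tsv(regs, out / "regulons.tsv")
    pd.DataFrame(
        [
            {"ligand": s.ligand, "receptor": s.receptor, "family": "CCL"}
            for s in cfg.lr_specs
        ]
    ).to_csv(out / "lr_pairs.tsv", sep="\t", index=False)
    truth.cluster_markers.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
    truth.genotype_de.to_csv(out / "truth_genotype_de.tsv", sep="\t", index=False)
    truth.doublets.rename("is_doublet").to_frame().reset_index(names="cell_id").to_csv(
        out / "truth_doublets.tsv", sep="\t", index=False
    )
    return cfg
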