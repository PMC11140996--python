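"""One-config orchestration of the desk-scale workflow:

    simulate -> qc -> cluster -> cnv -> deg -> scores -> roe

Every stage's parameters live in one config block; all randomness flows from
the single global seed through named per-stage substreams, so identical
config + seed reproduces every output byte for byte. Stage outputs are
written as TSV as they are produced, and a summary ``report.json`` collects
the QC funnel, the malignant-call confusion matrix against planted truth,
the recovered context gene sets against the planted programs, and the Ro/e
table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ctxneu import cluster as _cluster
from ctxneu import cnv as _cnv
from ctxneu import dge as _dge
from ctxneu import pref as _pref
from ctxneu import qc as _qc
from ctxneu import scores as _scores
from ctxneu.io import read_dataset, write_dataset
from ctxneu.simulate import SyntheticDesign, default_design

__all__ = ["PipelineConfig", "ConfigError", "StageError", "default_config", "run_pipeline"]

logger = logging.getLogger("ctxneu")

CONFIG_VERSION = 1

_STAGES = ("simulate", "qc", "cluster", "cnv", "deg", "scores", "roe")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    """The bundled demo configuration: the default synthetic design and the
    printed parameter defaults of every stage (min_genes 250, max_mito 0.30,
    2 doublet votes, window 100, cutoff 0.1, CNV threshold 0.04, fold change
    1.2, p 0.001, top_n 21)."""
    return {
        "version": CONFIG_VERSION,
        "seed": 0,
        "simulate": {"input_dir": None, "design": None, "write_counts": False},
        "qc": {
            "min_genes": 250,
            "max_mito": 0.30,
            "doublet_votes": 2,
            "doublet_threshold": 0.5,
            "detector_k": [15, 30],
            "n_simulated_per_cell": 0.25,
        },
        "cluster": {"n_hvg": 2000, "n_pcs": 30, "resolution": 0.8, "k_neighbors": 15},
        "cnv": {
            "window": 100,
            "cutoff": 0.1,
            "clip": 3.0,
            "threshold": 0.04,
            "cell_type_col": "true_cell_type",
            "query_cell_type": "epithelial",
            "reference_tissues": ["peritumor"],
        },
        "deg": {
            "cell_type": "neutrophil",
            "group_by": "tissue",
            "contrast": ["tumor", "peritumor"],
            "test": "bimod",
            "fc_threshold": 1.2,
            "p_threshold": 0.001,
        },
        "scores": {"cell_type": "neutrophil", "top_n": 21, "tissue_map": None},
        "roe": {"tissue_col": "tissue"},
    }


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    raw: dict = dc_field(default_factory=default_config)

    def __post_init__(self) -> None:
        defaults = default_config()
        unknown = set(self.raw) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        merged = {}
        for key, dflt in defaults.items():
            value = self.raw.get(key, dflt)
            if isinstance(dflt, dict):
                extra = set(value) - set(dflt)
                if extra:
                    raise ConfigError(f"unknown keys in {key!r} block: {sorted(extra)}")
                merged[key] = {**dflt, **value}
            else:
                merged[key] = value
        if merged["version"] != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {merged['version']!r}")
        if not isinstance(merged["seed"], (int, np.integer)):
            raise ConfigError("seed must be an integer")
        self.raw = merged

    def __getitem__(self, key: str):
        return self.raw[key]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not hold a mapping")
        return cls(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(int(global_seed), spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _write_tsv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig | dict, out_dir) -> Path:
    """Execute the full workflow; returns the report directory.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seed = int(config["seed"])
    report: dict = {"seed": seed, "stages": {}}
    config.to_yaml(out / "config_used.yaml")

    try:
        # ---- simulate / load ------------------------------------------------
        stage = "simulate"
        try:
            sim_cfg = config["simulate"]
            if sim_cfg.get("input_dir"):
                adata = read_dataset(sim_cfg["input_dir"])
                logger.info("loaded %d cells x %d genes from %s", adata.n_obs, adata.n_vars, sim_cfg["input_dir"])
            else:
                if sim_cfg.get("design"):
                    design = SyntheticDesign.from_dict(sim_cfg["design"])
                    design.seed = _stage_seed(seed, "simulate")
                else:
                    design = default_design(seed=_stage_seed(seed, "simulate"))
                from ctxneu.simulate import generate_dataset

                adata = generate_dataset(design)
                logger.info("simulated %d cells x %d genes", adata.n_obs, adata.n_vars)
                if sim_cfg.get("write_counts"):
                    write_dataset(adata, out / "counts", overwrite=True)
            report["stages"]["simulate"] = {"n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars)}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # ---- qc --------------------------------------------------------------
        stage = "qc"
        try:
            qc_cfg = config["qc"]
            qc_report = _qc.compute_cell_qc(
                adata, min_genes=qc_cfg["min_genes"], max_mito=qc_cfg["max_mito"]
            )
            qc_seed = _stage_seed(seed, "qc")
            n_sim = int(round(qc_cfg["n_simulated_per_cell"] * adata.n_obs))
            detector_scores = [
                _qc.score_doublets_simulated(
                    adata, n_simulated=n_sim, k_neighbors=k, seed=qc_seed + i, sample_key="patient"
                )
                for i, k in enumerate(qc_cfg["detector_k"])
            ]
            flags, votes = _qc.consensus_doublet_call(
                detector_scores,
                thresholds=qc_cfg["doublet_threshold"],
                min_votes=qc_cfg["doublet_votes"],
            )
            qc_report = _qc.apply_qc(qc_report, flags, votes)
            _write_tsv(qc_report.table, out / "qc_report.tsv", index_label="cell_id")
            funnel = qc_report.table["reason"].value_counts().to_dict()
            report["stages"]["qc"] = {
                "n_pass": qc_report.n_pass,
                "n_fail": qc_report.n_fail,
                "funnel": {k: int(v) for k, v in sorted(funnel.items())},
            }
            passing = qc_report.passing_cells()
            clean = adata[passing].copy()
            logger.info("QC: %d/%d cells pass", qc_report.n_pass, adata.n_obs)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # ---- cluster ---------------------------------------------------------
        stage = "cluster"
        try:
            cl_cfg = config["cluster"]
            assignment = _cluster.cluster_cells(
                clean,
                n_hvg=cl_cfg["n_hvg"],
                n_pcs=cl_cfg["n_pcs"],
                resolution=cl_cfg["resolution"],
                k_neighbors=cl_cfg["k_neighbors"],
                seed=_stage_seed(seed, "cluster"),
            )
            clean.obs["cluster"] = assignment.labels
            _write_tsv(assignment.labels.to_frame(), out / "clusters.tsv", index_label="cell_id")
            report["stages"]["cluster"] = {
                "n_clusters": assignment.n_clusters,
                "parameters": assignment.parameters,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # ---- cnv -------------------------------------------------------------
        stage = "cnv"
        try:
            cnv_cfg = config["cnv"]
            ct_col = cnv_cfg["cell_type_col"]
            is_query_type = clean.obs[ct_col].astype(str) == cnv_cfg["query_cell_type"]
            epi = clean[is_query_type].copy()
            ref_mask = epi.obs["tissue"].isin(cnv_cfg["reference_tissues"])
            if "true_is_malignant" in epi.obs:
                ref_mask &= ~epi.obs["true_is_malignant"]
            profile = _cnv.infer_malignant(
                epi,
                reference_cells=epi.obs_names[ref_mask],
                window_size=cnv_cfg["window"],
                expression_cutoff=cnv_cfg["cutoff"],
                clip=cnv_cfg["clip"],
                threshold=cnv_cfg["threshold"],
            )
            frame = profile.to_frame()
            _write_tsv(frame, out / "cnv_scores.tsv", index_label="cell_id")
            cnv_summary = {
                "n_cells": int(len(frame)),
                "n_malignant": int(frame["is_malignant"].sum()),
                "n_windows": len(profile.windows),
            }
            if "true_is_malignant" in epi.obs:
                truth = epi.obs["true_is_malignant"].to_numpy()
                called = frame["is_malignant"].to_numpy()
                tp = int(np.sum(truth & called))
                fn = int(np.sum(truth & ~called))
                fp = int(np.sum(~truth & called))
                tn = int(np.sum(~truth & ~called))
                cnv_summary["confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
                cnv_summary["sensitivity"] = tp / max(tp + fn, 1)
                cnv_summary["specificity"] = tn / max(tn + fp, 1)
            report["stages"]["cnv"] = cnv_summary
            logger.info("CNV: %d/%d cells called malignant", cnv_summary["n_malignant"], len(frame))
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # ---- deg -------------------------------------------------------------
        stage = "deg"
        try:
            deg_cfg = config["deg"]
            sub = clean[clean.obs[ct_col].astype(str) == deg_cfg["cell_type"]].copy()
            table = _dge.find_degs(
                sub,
                deg_cfg["group_by"],
                tuple(deg_cfg["contrast"]),
                fc_threshold=deg_cfg["fc_threshold"],
                p_threshold=deg_cfg["p_threshold"],
                test=deg_cfg["test"],
            )
            _write_tsv(table.frame, out / "degs.tsv", index_label="gene_id")
            report["stages"]["deg"] = {
                "contrast": list(table.contrast),
                "n_significant": int(table.frame["significant"].sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # ---- scores ----------------------------------------------------------
        stage = "scores"
        try:
            sc_cfg = config["scores"]
            neu = clean[clean.obs[ct_col].astype(str) == sc_cfg["cell_type"]].copy()
            css = _scores.build_context_scores(
                neu,
                tissue_label_map=sc_cfg["tissue_map"] or "tissue",
                top_n=sc_cfg["top_n"],
            )
            _write_tsv(css.scores, out / "context_scores.tsv", index_label="cell_id")
            sets_dir = out / "gene_sets"
            sets_dir.mkdir(exist_ok=True)
            for set_name, genes in css.gene_sets().items():
                (sets_dir / f"{set_name}.txt").write_text("".join(f"{g}\n" for g in genes))
            summary = {name: len(genes) for name, genes in css.gene_sets().items()}
            summary["mean_score_by_context"] = {
                name: {
                    ctx: float(np.round(css.scores.loc[css.scores["context"] == ctx, name].mean(), 6))
                    for ctx in ("blood", "peritumor", "tumor")
                }
                for name in ("nontumor_activating", "tissue_residing", "tumor_modifying")
            }
            if "design" in adata.uns:
                planted = {
                    p["name"]: set(p["genes"]) for p in adata.uns["design"].get("programs", [])
                }
                recovery = {}
                for set_name, planted_name in [
                    ("nontumor_activating", "nontumor_shared"),
                    ("tissue_residing", "tissue_shared"),
                    ("tumor_modifying", "tumor_specific"),
                ]:
                    if planted_name in planted:
                        got = set(css.gene_sets()[set_name])
                        denom = min(sc_cfg["top_n"], len(planted[planted_name]))
                        recovery[set_name] = len(got & planted[planted_name]) / denom
                summary["planted_program_recovery"] = recovery
            report["stages"]["scores"] = summary
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # ---- roe -------------------------------------------------------------
        stage = "roe"
        try:
            roe_cfg = config["roe"]
            result = _pref.roe(clean.obs["cluster"], clean.obs[roe_cfg["tissue_col"]])
            _write_tsv(result.to_frame(), out / "roe.tsv", index_label="cluster")
            report["stages"]["roe"] = {
                "n_clusters": int(result.ratio.shape[0]),
                "n_tissues": int(result.ratio.shape[1]),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
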