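"""End-to-end orchestration: config schema, stage sequencing, run summary.

A pipeline config is a flat YAML file with one section per stage::

    io:        {outdir: results/}
    simdata:   {seed: 7, n_proteins: 2000, ...}          # optional
    preprocess: {imputation: half-minimum, ...}
    diffabund: {mode: fdr_and_fc, sd_multiple: 2.0, fdr_cut: 0.05, ...}
    kinases:   {n_top: 200, pu_rounds: 50, ...}
    comodules: {min_size: 50, merge_cut: 0.25, ...}
    enrich:    {gmt: sets.gmt, min_size: 10, ...}        # optional

Unknown sections or keys raise a validation error naming the key. Every
stage writes its TSV outputs with a provenance sidecar; a failing stage
aborts the run with the stage name, leaving partial outputs plus a FAILED
marker file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import comodules, diffabund, enrich, io, kinases, simdata

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown key, bad value)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


_SCHEMA: dict[str, set[str]] = {
    "io": {"outdir"},
    "simdata": {f.name for f in dataclasses.fields(simdata.SimConfig)},
    "preprocess": {"imputation", "min_nonmissing_per_group", "already_log2"},
    "diffabund": {"mode", "sd_multiple", "fdr_cut", "p_cut", "sd_method",
                  "n_perm", "seed"},
    "kinases": {"n_top", "pu_rounds", "score_weight", "ranking_key", "seed",
                "stable_fraction", "batch_correct", "consensus_fdr_cut",
                "consensus_sd_multiple"},
    "comodules": {"min_size", "merge_cut", "r2_target", "max_mean_k",
                  "mm_cut", "ps_cut", "power", "powers"},
    "enrich": {"gmt", "min_size", "max_size", "n_perm", "seed", "mode",
               "p_cut", "q_cut", "id_mapping"},
    "qc": {"pca_screen", "k_sd"},
}


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping of stage sections")
    for section, content in config.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in content:
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key {key!r} in section {section!r}")
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def run_pipeline(
    config: dict,
    outdir: Optional[Path] = None,
    protein_matrix: Optional[pd.DataFrame] = None,
    phospho_matrix: Optional[pd.DataFrame] = None,
    meta: Optional[pd.DataFrame] = None,
    site_table: Optional[pd.DataFrame] = None,
    pssms: Optional[pd.DataFrame] = None,
    annotation: Optional[pd.DataFrame] = None,
) -> dict:
    """Execute simdata (optional) -> preprocess -> diffabund -> kinases ->
    comodules -> enrichment, writing artifacts and a run summary.

    Inputs not passed in memory must come from a ``simdata`` section in the
    config. Returns the summary dict (also written to ``summary.json``).
    """
    config = validate_config(dict(config))
    outdir = Path(outdir or config.get("io", {}).get("outdir", "phosnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    summary: dict = {"stages": []}

    def fail(stage: str, exc: Exception):
        failed_marker.write_text(f"failed at stage: {stage}\n{exc}\n")
        raise StageError(stage, exc)

    # ---- simdata ----------------------------------------------------------
    if protein_matrix is None or meta is None:
        try:
            sim_cfg = simdata.SimConfig(**(config.get("simdata") or {}))
            ds = simdata.simulate_dataset(sim_cfg)
            io.write_dataset(ds, outdir / "simdata")
            protein_matrix, phospho_matrix = ds.protein_matrix, ds.phospho_matrix
            meta, site_table = ds.meta, ds.site_table
            pssms, annotation = ds.pssms, ds.annotation
            summary["stages"].append("simdata")
            summary["simdata"] = {"seed": sim_cfg.seed,
                                  "n_proteins": sim_cfg.n_proteins,
                                  "n_phosphosites": sim_cfg.n_phosphosites}
        except Exception as exc:  # noqa: BLE001
            fail("simdata", exc)

    groups = meta["group"]
    trait = meta["trait"]

    # ---- preprocess --------------------------------------------------------
    try:
        pre_cfg = config.get("preprocess") or {}
        options = diffabund.PreprocessOptions(
            already_log2=pre_cfg.get("already_log2", True),
            imputation=pre_cfg.get("imputation", "half-minimum"),
            min_nonmissing_per_group=pre_cfg.get("min_nonmissing_per_group", 2),
        )
        protein_matrix, prov_p = diffabund.preprocess(protein_matrix, groups, options)
        io.write_matrix(protein_matrix, outdir / "protein_preprocessed.tsv",
                        stage="preprocess", params=prov_p)
        if phospho_matrix is not None:
            phospho_matrix, prov_s = diffabund.preprocess(phospho_matrix, groups, options)
            io.write_matrix(phospho_matrix, outdir / "phospho_preprocessed.tsv",
                            stage="preprocess", params=prov_s)
        summary["stages"].append("preprocess")
    except Exception as exc:  # noqa: BLE001
        fail("preprocess", exc)

    # ---- qc (optional PCA screen) ------------------------------------------
    qc_cfg = config.get("qc") or {}
    if qc_cfg.get("pca_screen", False):
        try:
            flags = enrich.pca_outlier_screen(protein_matrix, groups,
                                              k_sd=qc_cfg.get("k_sd", 3.0))
            io.write_stats(flags, outdir / "pca_screen.tsv", "qc",
                           params=qc_cfg)
            summary["qc_flagged"] = flags.index[flags["flagged"]].tolist()
            summary["stages"].append("qc")
        except Exception as exc:  # noqa: BLE001
            fail("qc", exc)

    # ---- diffabund ---------------------------------------------------------
    try:
        da_cfg = config.get("diffabund") or {}
        spec = diffabund.ThresholdSpec(
            fdr_cut=da_cfg.get("fdr_cut", 0.05),
            p_cut=da_cfg.get("p_cut", 0.05),
            sd_multiple=da_cfg.get("sd_multiple", 2.0),
            mode=da_cfg.get("mode", "fdr_and_fc"),
        )
        called, da_summary = diffabund.differential_abundance(
            protein_matrix, groups, spec,
            sd_method=da_cfg.get("sd_method", "trimmed_ml"),
            n_perm=da_cfg.get("n_perm", 100),
            seed=da_cfg.get("seed", 0),
        )
        io.write_stats(
            called[["log2fc", "t_mod", "p", "q_bh", "call"]],
            outdir / "protein_stats.tsv", "diffabund", params=da_cfg)
        summary["protein_diffabund"] = da_summary
        phospho_called = None
        if phospho_matrix is not None:
            phospho_called, ph_summary = diffabund.differential_abundance(
                phospho_matrix, groups, spec,
                sd_method=da_cfg.get("sd_method", "trimmed_ml"),
                n_perm=da_cfg.get("n_perm", 100),
                seed=da_cfg.get("seed", 0),
            )
            io.write_stats(
                phospho_called[["log2fc", "t_mod", "p", "q_bh", "call"]],
                outdir / "phospho_stats.tsv", "diffabund", params=da_cfg)
            summary["phospho_diffabund"] = ph_summary
        summary["stages"].append("diffabund")
    except Exception as exc:  # noqa: BLE001
        fail("diffabund", exc)

    # ---- kinases -----------------------------------------------------------
    if phospho_matrix is not None and site_table is not None \
            and pssms is not None and annotation is not None:
        try:
            kin_cfg = config.get("kinases") or {}
            norm_stats = kinases.normalize_site_by_protein(
                phospho_matrix, protein_matrix, site_table, groups)
            norm_profiles, _ = kinases.site_minus_protein_profiles(
                phospho_matrix, protein_matrix, site_table)
            scores = kinases.score_substrates(
                phospho_matrix, site_table, pssms, annotation,
                weight=kin_cfg.get("score_weight", 0.5))
            scores = kinases.pu_predict(scores, n_rounds=kin_cfg.get("pu_rounds", 50),
                                        seed=kin_cfg.get("seed", 0))
            activities = kinases.infer_kinase_activities(
                norm_stats, scores,
                n_top=kin_cfg.get("n_top", 200),
                key=kin_cfg.get("ranking_key", "pu_probability"),
                norm_profiles=norm_profiles, groups=groups)
            io.write_stats(norm_stats, outdir / "phospho_normalized_stats.tsv",
                           "kinases", params=kin_cfg)
            io.write_stats(scores, outdir / "substrate_scores.tsv",
                           "kinases", params=kin_cfg)
            io.write_stats(activities, outdir / "kinase_activity.tsv",
                           "kinases", params=kin_cfg)
            summary["kinase_directions"] = activities["direction"].to_dict()
            summary["stages"].append("kinases")
        except Exception as exc:  # noqa: BLE001
            fail("kinases", exc)

    # ---- comodules ---------------------------------------------------------
    try:
        co_cfg = config.get("comodules") or {}
        powers = co_cfg.get("powers")
        net = comodules.coexpression_analysis(
            protein_matrix, trait,
            min_size=co_cfg.get("min_size", 50),
            merge_cut=co_cfg.get("merge_cut", 0.25),
            powers=tuple(powers) if powers else tuple(range(1, 21)),
            r2_target=co_cfg.get("r2_target", 0.85),
            max_mean_k=co_cfg.get("max_mean_k", 100.0),
            mm_cut=co_cfg.get("mm_cut", 0.8),
            ps_cut=co_cfg.get("ps_cut", 0.5),
            power=co_cfg.get("power"),
        )
        io.write_stats(net.scan.scan.set_index("power"),
                       outdir / "soft_threshold_scan.tsv", "comodules",
                       params=co_cfg)
        io.write_stats(net.module_set.eigengenes, outdir / "eigengenes.tsv",
                       "comodules", params=co_cfg)
        io.write_stats(net.trait_stats, outdir / "module_trait.tsv",
                       "comodules", params=co_cfg)
        io.write_stats(net.membership, outdir / "module_membership.tsv",
                       "comodules", params=co_cfg)
        summary["comodules"] = {
            "chosen_power": net.scan.chosen_power,
            "n_modules": len(net.module_set.module_ids),
            "module_sizes": net.module_set.sizes(),
            "top_module_by_trait": (
                int(net.trait_stats["r"].abs().idxmax())
                if len(net.trait_stats) else None),
            "n_hubs": len(net.hubs),
        }
        summary["stages"].append("comodules")
    except Exception as exc:  # noqa: BLE001
        fail("comodules", exc)

    # ---- enrichment --------------------------------------------------------
    en_cfg = config.get("enrich") or {}
    if en_cfg.get("gmt"):
        try:
            collection = enrich.read_gmt(en_cfg["gmt"])
            universe = protein_matrix.index.tolist()
            query = called.index[called["call"] != "null"].tolist()
            if en_cfg.get("id_mapping"):
                mapping = pd.read_csv(en_cfg["id_mapping"], sep="\t")
                universe = enrich.apply_id_mapping(universe, mapping)
                query = enrich.apply_id_mapping(query, mapping)
            ora = enrich.ora_test(query, collection, universe)
            io.write_stats(ora, outdir / "ora.tsv", "enrich", params=en_cfg)
            summary["top_ora_terms"] = ora.index[:10].tolist()
            if en_cfg.get("mode", "ora") in ("gsea", "both"):
                ranking = called["log2fc"].dropna()
                gsea = enrich.gsea_score(
                    ranking, collection,
                    n_perm=en_cfg.get("n_perm", 200),
                    seed=en_cfg.get("seed", 0),
                    min_size=en_cfg.get("min_size", 10),
                    max_size=en_cfg.get("max_size", 500))
                io.write_stats(gsea, outdir / "gsea.tsv", "enrich", params=en_cfg)
                summary["top_gsea_terms"] = gsea.index[:10].tolist()
            summary["stages"].append("enrich")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("enrich", exc)

    (outdir / "summary.json").write_text(
        json.dumps(io._jsonable(summary), indent=2, sort_keys=True) + "\n")
    return summary
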