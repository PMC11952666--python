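"""TSV / JSON readers and writers plus provenance sidecars.

All tabular artifacts are plain TSV: intensity matrices (rows = features,
first column ``feature_id``), sample metadata (sample, group, trait, batch),
site tables, PSSMs, kinase-substrate annotations and per-stage statistics.
Every writer can attach a ``<file>.prov.json`` sidecar recording the
parameters needed to regenerate the file; sidecars contain no timestamps so
identical runs produce byte-identical trees.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .simdata import GroundTruth, SimulatedDataset

_FLOAT_FMT = "%.10g"


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, stage: str, params: dict,
                     inputs: Optional[dict[str, str]] = None) -> Path:
    """Write ``<path>.prov.json`` describing how ``path`` was produced."""
    sidecar = Path(str(path) + ".prov.json")
    record = {
        "stage": stage,
        "output": Path(path).name,
        "package": "phosnet",
        "version": __version__,
        "params": _jsonable(params),
        "input_hashes": inputs or {},
    }
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def write_matrix(matrix: pd.DataFrame, path, stage: str = "matrix",
                 params: Optional[dict] = None) -> None:
    df = matrix.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    write_provenance(path, stage, params or {})


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_metadata(meta: pd.DataFrame, path, params: Optional[dict] = None) -> None:
    meta.to_csv(path, sep="\t")
    write_provenance(path, "metadata", params or {})


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_site_table(site_table: pd.DataFrame, path,
                     params: Optional[dict] = None) -> None:
    site_table.to_csv(path, sep="\t")
    write_provenance(path, "site_table", params or {})


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site_id")


def write_pssms(pssms: pd.DataFrame, path, params: Optional[dict] = None) -> None:
    pssms.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    write_provenance(path, "pssms", params or {})


def read_pssms(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=["kinase", "position"])


def write_annotation(annotation: pd.DataFrame, path,
                     params: Optional[dict] = None) -> None:
    annotation.to_csv(path, sep="\t", index=False)
    write_provenance(path, "annotation", params or {})


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(gt: GroundTruth, path) -> None:
    record = {
        "de_labels": gt.de_labels.to_dict(),
        "kinase_shifts": _jsonable(gt.kinase_shifts),
        "substrate_map": _jsonable(gt.substrate_map),
        "module_labels": {k: int(v) for k, v in gt.module_labels.items()},
        "latent_factors": {
            m: gt.latent_factors.loc[m].to_dict()
            for m in gt.latent_factors.index
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def write_stats(stats_df: pd.DataFrame, path, stage: str,
                params: Optional[dict] = None,
                inputs: Optional[dict[str, str]] = None) -> None:
    stats_df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    write_provenance(path, stage, params or {}, inputs)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write all simulated artifacts of one dataset into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _jsonable(vars(dataset.config))
    paths = {
        "protein_matrix": outdir / "protein_matrix.tsv",
        "phospho_matrix": outdir / "phospho_matrix.tsv",
        "meta": outdir / "samples.tsv",
        "site_table": outdir / "sites.tsv",
        "pssms": outdir / "pssms.tsv",
        "annotation": outdir / "known_substrates.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_matrix(dataset.protein_matrix, paths["protein_matrix"],
                 stage="simdata", params=cfg)
    write_matrix(dataset.phospho_matrix, paths["phospho_matrix"],
                 stage="simdata", params=cfg)
    write_metadata(dataset.meta, paths["meta"], params=cfg)
    write_site_table(dataset.site_table, paths["site_table"], params=cfg)
    write_pssms(dataset.pssms, paths["pssms"], params=cfg)
    write_annotation(dataset.annotation, paths["annotation"], params=cfg)
    write_ground_truth(dataset.ground_truth, paths["ground_truth"])
    return paths
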