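"""File formats: NIfTI stacks, covariate tables, model containers.

Conventions: voxel indices are 0-based; volumes are flattened in
row-major (C) order; masks must share the data grid exactly (no
resampling); ages are in years and volumes in milliliters (or the
simulator's modulated-volume units). Covariate CSVs carry one header row,
one row per subject, and a ``subject_id`` column that joins images to
rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .boxcox import BoxCoxModel
from .engine import (
    GLOBAL_SCHEMA,
    LOCAL_SCHEMA,
    EngineConfig,
    GlobalModelSet,
    VoxelModelSet,
)
from .gp import FitConfig, TrainedGP

__all__ = [
    "read_covariates",
    "read_image_stack",
    "write_volume",
    "save_model_set",
    "load_model_set",
    "save_global_models",
    "load_global_models",
]

CONTAINER_VERSION = 1

# default string codings for the binary covariates
SEX_LABELS = {"f": 0, "female": 0, "m": 1, "male": 1, "0": 0, "1": 1}
FSTR_LABELS = {"1.5t": 0, "3t": 1, "0": 0, "1": 1}


def _map_binary(series: pd.Series, labels: dict, column: str) -> pd.Series:
    if series.dtype.kind in "ifub":
        vals = series.astype(float)
    else:
        key = series.astype(str).str.strip().str.lower()
        unknown = sorted(set(key) - set(labels))
        if unknown:
            raise ValueError(f"column {column!r} has unmapped labels: {unknown}")
        vals = key.map(labels).astype(float)
    bad = sorted(set(vals.unique()) - {0.0, 1.0})
    if bad:
        raise ValueError(f"column {column!r} must be coded 0/1, found values {bad}")
    return vals


def read_covariates(path, schema: str | list[str] | None = None) -> pd.DataFrame:
    """Read and validate a covariate CSV.

    ``schema`` may be "local" ([age, sex, tgmv, twmv, tcsf, fstr]),
    "global" ([age, sex, ticv, fstr]; ticv is derived from the three
    tissue volumes when absent), an explicit column list, or None (keep
    all columns). Header order is irrelevant; sex/fstr accept {0,1} or
    standard string labels. Errors name any missing column, non-finite
    value or duplicate subject id.
    """
    df = pd.read_csv(path)
    if "subject_id" in df.columns:
        dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate subject ids: {dup}")
    if schema == "local":
        cols = list(LOCAL_SCHEMA)
    elif schema == "global":
        cols = list(GLOBAL_SCHEMA)
        if "ticv" not in df.columns:
            need = [c for c in ("tgmv", "twmv", "tcsf") if c not in df.columns]
            if need:
                raise ValueError(
                    f"covariate file is missing column 'ticv' and cannot derive it "
                    f"(also missing {need})"
                )
            df["ticv"] = df["tgmv"] + df["twmv"] + df["tcsf"]
    elif schema is None:
        cols = [c for c in df.columns if c != "subject_id"]
    else:
        cols = list(schema)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"covariate file is missing columns: {missing}")
    if "sex" in cols:
        df["sex"] = _map_binary(df["sex"], SEX_LABELS, "sex")
    if "fstr" in cols:
        df["fstr"] = _map_binary(df["fstr"], FSTR_LABELS, "fstr")
    out = df[(["subject_id"] if "subject_id" in df.columns else []) + cols].copy()
    num = out[cols].apply(pd.to_numeric)
    if not np.all(np.isfinite(num.to_numpy(dtype=float))):
        bad = [c for c in cols if not np.all(np.isfinite(num[c].to_numpy(dtype=float)))]
        raise ValueError(f"non-finite covariate values in columns: {bad}")
    out[cols] = num
    return out


def read_image_stack(paths, covariates: pd.DataFrame | None = None, id_column: str = "subject_id"):
    """Load a 4-D NIfTI or a list of per-subject 3-D NIfTIs.

    Returns ``(Y, shape, affine, ids)`` with ``Y`` of shape
    (n_subjects, n_voxels), voxels in row-major order. All volumes must
    share grid shape and affine (1e-4 tolerance). With a list of files,
    subject ids are the file stems and rows are reordered to match
    ``covariates[id_column]``; unmatched ids on either side are a hard
    error listing the offenders.
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D image, got shape {data.shape}")
        shape = data.shape[:3]
        # row-major voxel order within each volume
        Y = np.stack([data[..., i].ravel() for i in range(data.shape[3])])
        ids = None
        if covariates is not None:
            if len(covariates) != Y.shape[0]:
                raise ValueError(
                    f"4-D image holds {Y.shape[0]} volumes but covariate table has "
                    f"{len(covariates)} rows"
                )
            ids = covariates[id_column].tolist() if id_column in covariates else None
        return Y, shape, img.affine, ids

    paths = [Path(p) for p in paths]
    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        d = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape, affine = d.shape, img.affine
        else:
            if d.shape != shape:
                raise ValueError(f"grid mismatch: {p.name} has shape {d.shape}, expected {shape}")
            if not np.allclose(img.affine, affine, atol=1e-4):
                raise ValueError(f"affine mismatch in {p.name}")
        vols.append(d.ravel())
    ids = [p.name.split(".")[0] for p in paths]
    Y = np.stack(vols)
    if covariates is not None:
        if id_column not in covariates:
            raise ValueError(f"covariate table lacks the {id_column!r} column")
        table_ids = covariates[id_column].astype(str).tolist()
        missing_img = sorted(set(table_ids) - set(ids))
        missing_row = sorted(set(ids) - set(table_ids))
        if missing_img or missing_row:
            raise ValueError(
                f"image/covariate id mismatch; no image for {missing_img}, "
                f"no covariate row for {missing_row}"
            )
        order = [ids.index(t) for t in table_ids]
        Y = Y[order]
        ids = table_ids
    return Y, shape, affine, ids


def write_volume(path, volume: np.ndarray, affine: np.ndarray | None = None) -> Path:
    """Write one 3-D volume as NIfTI-1."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine if affine is not None else np.eye(4)), path)
    return path


def _fit_config_dict(fc: FitConfig) -> dict:
    return {"n_restarts": fc.n_restarts, "max_iter": fc.max_iter, "gtol": fc.gtol}


def save_model_set(path, models: VoxelModelSet) -> Path:
    """Serialize a voxel model set to a versioned JSON container."""
    doc = {
        "format_version": CONTAINER_VERSION,
        "kind": "voxel_model_set",
        "covariate_schema": models.covariate_schema,
        "mask_shape": list(models.mask.shape),
        "mask_flat": models.mask.ravel().astype(int).tolist(),
        "seed": models.seed,
        "config": {
            "boxcox": models.config.boxcox,
            "boxcox_shift": models.config.boxcox_shift,
            "fit": _fit_config_dict(models.config.fit),
        },
        "evidence_map": models.evidence_map.tolist(),
        "noise_map": models.noise_map.tolist(),
        "train_X": None if models.train_X is None else models.train_X.to_numpy().tolist(),
        "train_Y": None if models.train_Y is None else models.train_Y.tolist(),
        "models": [
            None
            if entry is None
            else {
                "gp": entry[0].to_dict(),
                "boxcox": None if entry[1] is None else entry[1].to_dict(),
            }
            for entry in models.models
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model_set(path) -> VoxelModelSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "voxel_model_set":
        raise ValueError("not a voxel model container")
    if doc["format_version"] != CONTAINER_VERSION:
        raise ValueError(f"unsupported container version {doc['format_version']}")
    mask = np.asarray(doc["mask_flat"], dtype=bool).reshape(doc["mask_shape"])
    cfg = EngineConfig(
        boxcox=doc["config"]["boxcox"],
        boxcox_shift=doc["config"]["boxcox_shift"],
        fit=FitConfig(**doc["config"]["fit"]),
    )
    models = [
        None
        if entry is None
        else (
            TrainedGP.from_dict(entry["gp"]),
            None if entry["boxcox"] is None else BoxCoxModel.from_dict(entry["boxcox"]),
        )
        for entry in doc["models"]
    ]
    return VoxelModelSet(
        models=models,
        mask=mask,
        covariate_schema=list(doc["covariate_schema"]),
        evidence_map=np.asarray(doc["evidence_map"], dtype=float),
        noise_map=np.asarray(doc["noise_map"], dtype=float),
        config=cfg,
        train_X=None
        if doc["train_X"] is None
        else pd.DataFrame(doc["train_X"], columns=doc["covariate_schema"]),
        train_Y=None if doc["train_Y"] is None else np.asarray(doc["train_Y"], dtype=float),
        seed=doc["seed"],
    )


def save_global_models(path, models: GlobalModelSet) -> Path:
    doc = {
        "format_version": CONTAINER_VERSION,
        "kind": "global_model_set",
        "covariate_schema": models.covariate_schema,
        "models": {k: m.to_dict() for k, m in models.models.items()},
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_global_models(path) -> GlobalModelSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "global_model_set":
        raise ValueError("not a global model container")
    return GlobalModelSet(
        models={k: TrainedGP.from_dict(d) for k, d in doc["models"].items()},
        covariate_schema=list(doc["covariate_schema"]),
    )
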