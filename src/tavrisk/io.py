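"""File-format plumbing: cohort CSV, feature caches, checkpoints, provenance.

Cohort CSV contract: one row per patient; header names matching the schema;
measurement columns prefixed ``J_``; outcome column ``y`` in {0,1}; blank or
NaN cells mean *missing* (mask false).  Binary covariate cells must be 0, 1
or blank.  Feature caches are CSV keyed by ``patient_id`` with columns
``f_0..f_{d_f-1}``.  Checkpoints are a single NPZ container holding the flat
numeric arrays plus a JSON metadata record (schema, scalers, format version,
config hash) — loading refuses containers whose schema hash does not match
their content.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .schema import (
    BINARY,
    J_PREFIX,
    Cohort,
    ModelParams,
    PriorParams,
    Scaler,
    TabularSchema,
)

CHECKPOINT_FORMAT = 1

__all__ = [
    "read_cohort",
    "write_cohort",
    "cohort_from_dataframe",
    "infer_schema",
    "read_features_csv",
    "write_features_csv",
    "attach_features",
    "save_checkpoint",
    "load_checkpoint",
    "config_hash",
    "JsonlLogger",
]


def infer_schema(df: pd.DataFrame) -> TabularSchema:
    """Schema from a cohort frame: non-J, non-bookkeeping columns; a column
    whose observed values are all in {0,1} is binary, else continuous."""
    names, kinds = [], []
    for col in df.columns:
        if col in ("y", "patient_id") or col.startswith(J_PREFIX):
            continue
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        kind = BINARY if vals.isin([0, 1]).all() and len(vals) else "continuous"
        names.append(col)
        kinds.append(kind)
    return TabularSchema(tuple(names), tuple(kinds))


def cohort_from_dataframe(df: pd.DataFrame, schema: TabularSchema,
                          require_outcome: bool = True) -> Cohort:
    """Validate and convert a cohort frame into arrays + masks."""
    missing_cols = [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing covariate columns: {missing_cols}")
    n = len(df)
    A = np.full((n, schema.d_A), np.nan)
    for i, name in enumerate(schema.names):
        col = pd.to_numeric(df[name], errors="coerce")
        raw = df[name]
        bad = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            r = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric value {raw.iloc[r]!r} in column {name!r}, row {r}")
        if schema.kinds[i] == BINARY:
            obs = col.dropna()
            if not obs.isin([0, 1]).all():
                r = int(obs.index[~obs.isin([0, 1])][0])
                raise ValueError(
                    f"binary column {name!r} contains {col.iloc[r]!r} at row "
                    f"{r}; expected 0, 1 or blank")
        A[:, i] = col.to_numpy(dtype=float)
    A_mask = ~np.isnan(A)

    j_cols = [c for c in df.columns if c.startswith(J_PREFIX)]
    J = np.full((n, len(j_cols)), np.nan)
    for i, c in enumerate(j_cols):
        J[:, i] = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
    J_mask = ~np.isnan(J)

    y = None
    if "y" in df.columns:
        yv = pd.to_numeric(df["y"], errors="coerce")
        if yv.isna().any():
            raise ValueError("outcome column y contains blank entries")
        if not yv.isin([0, 1]).all():
            raise ValueError("outcome column y must be 0/1")
        y = yv.to_numpy(dtype=int)
    elif require_outcome:
        raise ValueError("cohort has no outcome column 'y'")

    ids = (df["patient_id"].to_numpy() if "patient_id" in df.columns
           else np.arange(n))
    has_image = np.zeros(n, dtype=bool)
    return Cohort(schema, A, A_mask, J, J_mask, has_image, None, y, ids)


def read_cohort(path, schema: Optional[TabularSchema] = None,
                require_outcome: bool = True) -> Cohort:
    df = pd.read_csv(path)
    schema = schema or infer_schema(df)
    return cohort_from_dataframe(df, schema, require_outcome)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature caches
# ---------------------------------------------------------------------------

def write_features_csv(path, ids, F: np.ndarray) -> None:
    df = pd.DataFrame(F, columns=[f"f_{i}" for i in range(F.shape[1])])
    df.insert(0, "patient_id", ids)
    df.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("feature cache must carry a patient_id column")
    return df


def attach_features(cohort: Cohort, features: pd.DataFrame) -> Cohort:
    """Attach cached feature vectors by patient id; rows found in the cache
    become image-present."""
    fcols = [c for c in features.columns if c.startswith("f_")]
    lut = {pid: row for pid, row in
           zip(features["patient_id"], features[fcols].to_numpy(dtype=float))}
    out = cohort.copy()
    F = np.full((cohort.n, len(fcols)), np.nan)
    has = np.zeros(cohort.n, dtype=bool)
    for i, pid in enumerate(cohort.ids):
        if pid in lut:
            F[i] = lut[pid]
            has[i] = True
    out.F = F
    out.has_image = has
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _schema_hash(meta: dict) -> str:
    payload = json.dumps(meta["schema"], sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def save_checkpoint(path, params: ModelParams, prior: PriorParams,
                    schema: TabularSchema, scaler_A: Scaler, scaler_J: Scaler,
                    use_auxiliary_J: bool = True, seed: Optional[int] = None,
                    extra_meta: Optional[dict] = None) -> None:
    meta = {
        "format": CHECKPOINT_FORMAT,
        "schema": schema.to_dict(),
        "scaler_A": scaler_A.to_dict(),
        "scaler_J": scaler_J.to_dict(),
        "prior": prior.to_dict(),
        "use_auxiliary_J": bool(use_auxiliary_J),
        "seed": seed,
        "d_f": params.d_f,
        "d_J": params.d_J,
    }
    meta.update(extra_meta or {})
    meta["schema_sha256"] = _schema_hash(meta)
    np.savez(
        path,
        beta=params.beta, phi=params.phi, alpha_I=params.alpha_I,
        alpha_A=params.alpha_A,
        scalars=np.array([params.sigma_I, params.sigma_J, params.b_Y]),
        meta=np.array(json.dumps(meta)),
    )


def load_checkpoint(path):
    """Returns (params, prior, schema, scaler_A, scaler_J, meta).

    Refuses containers with an unknown format version or a schema that does
    not match its integrity hash (tampering / corruption)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format {meta.get('format')}")
        if meta.get("schema_sha256") != _schema_hash(meta):
            raise ValueError("checkpoint schema failed its integrity check")
        scalars = z["scalars"]
        params = ModelParams(
            beta=z["beta"], sigma_I=float(scalars[0]), phi=z["phi"],
            sigma_J=float(scalars[1]), alpha_I=z["alpha_I"],
            alpha_A=z["alpha_A"], b_Y=float(scalars[2]))
    schema = TabularSchema.from_dict(meta["schema"])
    prior = PriorParams.from_dict(meta["prior"])
    scaler_A = Scaler.from_dict(meta["scaler_A"])
    scaler_J = Scaler.from_dict(meta["scaler_J"])
    return params, prior, schema, scaler_A, scaler_J, meta


# ---------------------------------------------------------------------------
# provenance / logging
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration record."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class JsonlLogger:
    """Append-only JSONL event log used by the CLI commands."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, event: str, **fields) -> None:
        rec = {"event": event, "time": time.time(), **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
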