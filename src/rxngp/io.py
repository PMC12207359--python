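"""Dataset readers/writers, checkpoints, and run manifests.

The on-disk interchange formats are deliberately plain: reaction tables
are CSV with a fixed header, split manifests are JSON mapping task ids to
row indices, results are per-repeat CSV plus a 4-decimal aggregated view,
and checkpoints are NumPy archives with a JSON metadata entry.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .featurize import FeaturizationError, ReactionRecord
from .tasks import Task

__all__ = [
    "REACTION_COLUMNS",
    "read_reactions",
    "write_reactions",
    "write_results",
    "write_aggregate",
    "write_split_manifest",
    "read_split_manifest",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
]

REACTION_COLUMNS = [
    "reaction_id", "olefin_smiles", "ligand_smiles", "solvent_smiles",
    "metal", "additive", "temperature_c", "pressure_bar", "loading_molpct",
    "ee", "year",
]

#: abort reading when more than this fraction of rows fail validation
MAX_INVALID_FRACTION = 0.01


def read_reactions(path, max_invalid_fraction: float = MAX_INVALID_FRACTION):
    """Read and validate a reaction CSV into typed records.

    Invalid rows are collected with their (1-based, header-exclusive) row
    numbers; the run aborts if more than ``max_invalid_fraction`` of rows
    are invalid, otherwise offending rows are dropped with a report in
    the second return value.
    """
    df = pd.read_csv(path)
    missing = [c for c in REACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = ReactionRecord(
                reaction_id=str(row.reaction_id),
                olefin=str(row.olefin_smiles),
                ligand=str(row.ligand_smiles),
                solvent=str(row.solvent_smiles),
                metal=str(row.metal),
                additive_present=_parse_bool(row.additive),
                temperature=float(row.temperature_c),
                pressure=float(row.pressure_bar),
                catalyst_loading=float(row.loading_molpct),
                ee=float(row.ee),
                year=int(row.year),
            )
            rec.validate()
            records.append(rec)
        except (FeaturizationError, ValueError, TypeError) as exc:
            problems.append((i, str(exc)))
    if problems and len(problems) > max_invalid_fraction * len(df):
        head = "; ".join(f"row {i}: {msg}" for i, msg in problems[:5])
        raise ValueError(
            f"{len(problems)}/{len(df)} rows failed validation ({head} ...)")
    return records, problems


def _parse_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot interpret additive flag {v!r}")


def write_reactions(records, path):
    rows = []
    for r in records:
        rows.append({
            "reaction_id": r.reaction_id, "olefin_smiles": r.olefin,
            "ligand_smiles": r.ligand, "solvent_smiles": r.solvent,
            "metal": r.metal, "additive": int(r.additive_present),
            "temperature_c": r.temperature, "pressure_bar": r.pressure,
            "loading_molpct": r.catalyst_loading, "ee": r.ee, "year": r.year,
        })
    pd.DataFrame(rows, columns=REACTION_COLUMNS).to_csv(path, index=False)


def write_results(df: pd.DataFrame, path):
    """Per-repeat results CSV with a deterministic column order."""
    cols = ["method", "split_mode", "combination", "support_size",
            "repeat", "auprc"]
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False)


def write_aggregate(df: pd.DataFrame, path):
    """Aggregated results with floats rendered at 4 decimals."""
    df = df.copy()
    for col in ("mean_auprc", "dispersion"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False)


def write_split_manifest(split: dict, path):
    """Persist task index lists as JSON (task id -> rows)."""
    out = {}
    for role, tasks in split.items():
        if isinstance(tasks, Task):
            tasks = [tasks]
        if isinstance(tasks, (int, float)):
            out[role] = tasks
            continue
        out[role] = {t.task_id: t.indices.tolist() for t in tasks}
    Path(path).write_text(json.dumps(out, indent=1))


def read_split_manifest(path) -> dict:
    raw = json.loads(Path(path).read_text())
    out = {}
    for role, tasks in raw.items():
        if isinstance(tasks, (int, float)):
            out[role] = tasks
            continue
        out[role] = [Task(tid, np.asarray(idx, dtype=int), role.rstrip("s"))
                     for tid, idx in tasks.items()]
    return out


def save_checkpoint(path, model):
    """Serialize a fitted estimator: constructor params + fitted arrays."""
    meta = {
        "class": type(model).__name__,
        "params": _jsonable(model.get_params()),
        "version": __version__,
    }
    arrays = {}
    for name in ("theta_nn_", "theta_gp_", "phi_", "theta_gp_init_"):
        if hasattr(model, name):
            arrays[name] = np.asarray(getattr(model, name))
    for name in ("log_sigma2_", "sigma2_"):
        if hasattr(model, name):
            meta[name] = float(getattr(model, name))
    if hasattr(model, "extractor_"):
        meta["n_features"] = int(model.extractor_.in_dim)
    if hasattr(model, "_train_X"):
        arrays["train_X"] = model._train_X
        arrays["train_y"] = model._train_y
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    from . import estimators

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        arrays = {k: archive[k] for k in archive.files if k != "meta"}
    cls = getattr(estimators, meta["class"])
    params = dict(meta["params"])
    for k in ("hidden_sizes", "sigma2_bounds"):
        if k in params and isinstance(params[k], list):
            params[k] = tuple(params[k])
    model = cls(**params)
    if "train_X" in arrays:
        model._train_X = arrays.pop("train_X")
        model._train_y = arrays.pop("train_y")
    for k, v in arrays.items():
        setattr(model, k, v if v.ndim else float(v))
    for k in ("log_sigma2_", "sigma2_"):
        if k in meta:
            setattr(model, k, meta[k])
    if "n_features" in meta:
        model.extractor_ = model._make_extractor(int(meta["n_features"]))
    model.classes_ = np.array([0, 1])
    return model, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_manifest(path, config: dict, seeds: dict, inputs: dict | None = None):
    """Reproducibility manifest: config, seeds, code version, input hashes."""
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": _jsonable(config),
        "seeds": _jsonable(seeds),
        "input_hashes": {},
    }
    for name, p in (inputs or {}).items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        manifest["input_hashes"][name] = h
    Path(path).write_text(json.dumps(manifest, indent=1))
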