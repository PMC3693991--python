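"""CSV/JSON readers and writers for model tables, results and reports.

Model-table CSV dialect: columns ``id``, optional ``smiles``,
``fingerprint`` (a '0'/'1' string of the dataset-wide width), ``activity``,
optional ``logp``, then one ``pred_<MODEL>`` column per model.  Error
matrices are always recomputed on load, never trusted from file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import TableFormatError
from .models import Chemical, ModelTable
from .similarity import Fingerprint

__all__ = [
    "read_model_table",
    "write_model_table",
    "write_report",
    "write_results",
    "read_points_csv",
]

_PRED_PREFIX = "pred_"


def read_model_table(path: str | Path) -> ModelTable:
    """Load and validate a model table from CSV.

    The fingerprint width is inferred from the first row and enforced on all
    others; violations are reported with the offending row number.
    """
    df = pd.read_csv(
        path, dtype={"id": str, "fingerprint": str}, float_precision="round_trip"
    )
    required = {"id", "fingerprint", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    pred_cols = [c for c in df.columns if c.startswith(_PRED_PREFIX)]
    if len(pred_cols) < 2:
        raise TableFormatError(
            f"{path}: need at least two {_PRED_PREFIX}<MODEL> columns, found {pred_cols}"
        )
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise TableFormatError(f"{path}: duplicate chemical ids {dupes}")

    width: int | None = None
    chemicals: list[Chemical] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        fp_str = str(row.fingerprint)
        if width is None:
            width = len(fp_str)
        if len(fp_str) != width:
            raise TableFormatError(
                f"{path} row {row_no}: fingerprint width {len(fp_str)} != {width}"
            )
        try:
            fp = Fingerprint.from_string(fp_str)
        except Exception as exc:
            raise TableFormatError(f"{path} row {row_no}: {exc}") from exc
        logp = getattr(row, "logp", None)
        smiles = getattr(row, "smiles", None)
        chemicals.append(
            Chemical(
                id=str(row.id),
                fingerprint=fp,
                activity=float(row.activity),
                logp=None if logp is None or pd.isna(logp) else float(logp),
                smiles=None if smiles is None or pd.isna(smiles) else str(smiles),
            )
        )
    predictions = df[pred_cols].to_numpy(dtype=float)
    model_names = [c[len(_PRED_PREFIX):] for c in pred_cols]
    return ModelTable(chemicals, model_names, predictions)


def write_model_table(T: ModelTable, path: str | Path) -> None:
    """Write a model table in the CSV dialect (lossless round trip)."""
    data: dict[str, Any] = {
        "id": [c.id for c in T.chemicals],
    }
    if any(c.smiles is not None for c in T.chemicals):
        data["smiles"] = [c.smiles if c.smiles is not None else "" for c in T.chemicals]
    data["fingerprint"] = [c.fingerprint.to_string() for c in T.chemicals]
    data["activity"] = [repr(float(c.activity)) for c in T.chemicals]
    if any(c.logp is not None for c in T.chemicals):
        data["logp"] = [
            repr(float(c.logp)) if c.logp is not None else "" for c in T.chemicals
        ]
    for j, name in enumerate(T.model_names):
        data[f"{_PRED_PREFIX}{name}"] = [repr(float(v)) for v in T.predictions[:, j]]
    pd.DataFrame(data).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: Any, path: str | Path, config: dict | None = None) -> None:
    """Serialise a report to JSON with full-precision values and a config echo."""
    payload = {
        "package_version": __version__,
        "config": _jsonable(config or {}),
        "report": _jsonable(report),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_results(results: Any, path: str | Path, config: dict | None = None) -> None:
    """Serialise identification results (same JSON envelope as reports)."""
    write_report(results, path, config=config)


def read_points_csv(path: str | Path) -> list:
    """Read raw 2D points for the standalone front computation.

    Columns: compound_id, model_id, d, e.
    """
    from .pareto import TaggedPoint, Vector2D

    df = pd.read_csv(path, dtype={"compound_id": str, "model_id": str})
    missing = {"compound_id", "model_id", "d", "e"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        TaggedPoint(Vector2D(float(r.d), float(r.e)), str(r.compound_id), str(r.model_id))
        for r in df.itertuples(index=False)
    ]
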