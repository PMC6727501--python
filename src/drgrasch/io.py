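"""File I/O: claims CSV and norm-model JSON.

Claims travel as comma-delimited UTF-8 text with a header row and one
row per (case, item):

    case_id,drg,year,item,fee[,deducted]

A zero fee (or an absent row) means the case had no expenditure on the
item and is recorded as missing.  Calibrated models are stored as a
versioned JSON document holding, per DRG, each item's difficulty,
standard error and normalization bounds, plus the calibration settings.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import IO, Mapping

import pandas as pd

from .claims import (
    ClaimRecord,
    ClaimSet,
    ClaimsValidationError,
    NormalizationBounds,
)
from .rasch import ConvergenceReport, ItemCalibration, NormModel
from .schema import FeeItemSchema

CLAIMS_COLUMNS = ("case_id", "drg", "year", "item", "fee")
MODEL_FORMAT = "drgrasch-norm-model/1"


class ModelFormatError(ValueError):
    """Raised when a model file is unreadable, truncated, or the wrong
    version."""


def read_claims(
    source: str | Path | IO[str],
    schema: FeeItemSchema,
    role: str = "norm",
) -> ClaimSet:
    """Read a long-format claims CSV into a ClaimSet.

    Malformed rows (unknown item codes, negative or non-numeric fees,
    bad years) are collected and reported together with their input
    line numbers.  An empty file yields an empty ClaimSet.
    """
    try:
        df = pd.read_csv(
            source,
            dtype={"case_id": str, "drg": str, "item": str},
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return ClaimSet(schema=schema, records=[], role=role)
    missing_cols = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ClaimsValidationError(
            [f"missing required columns: {missing_cols}"]
        )
    has_labels = "deducted" in df.columns

    errors: list[str] = []
    cases: dict[tuple[str, str, int], ClaimRecord] = {}
    order: list[tuple[str, str, int]] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        item = row.item
        if item not in schema:
            errors.append(f"line {line}: unknown item code {item!r}")
            continue
        try:
            fee = float(row.fee)
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric fee {row.fee!r}")
            continue
        if math.isnan(fee):
            errors.append(f"line {line}: non-numeric fee {row.fee!r}")
            continue
        if fee < 0:
            errors.append(f"line {line}: negative fee {fee}")
            continue
        try:
            year = int(row.year)
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-integer year {row.year!r}")
            continue
        key = (row.case_id, row.drg, year)
        if key not in cases:
            cases[key] = ClaimRecord(
                case_id=row.case_id, drg_code=row.drg, year=year, fees={}
            )
            order.append(key)
        rec = cases[key]
        if fee > 0:
            rec.fees[item] = fee  # zero fee = no expenditure = missing
        if has_labels:
            raw = str(getattr(row, "deducted", "")).strip()
            if raw not in ("", "nan"):
                if raw not in ("0", "1", "True", "False", "true", "false"):
                    errors.append(
                        f"line {line}: deducted must be 0/1, got {raw!r}"
                    )
                    continue
                if rec.deducted is None:
                    rec.deducted = {}
                rec.deducted[item] = raw in ("1", "True", "true")
    if errors:
        raise ClaimsValidationError(errors)
    return ClaimSet(schema=schema, records=[cases[k] for k in order], role=role)


def write_claims(claims: ClaimSet, path: str | Path) -> None:
    """Write a ClaimSet as long-format CSV (inverse of ``read_claims``).

    Missing cells are omitted, labeled cells carry a 0/1 ``deducted``
    column; the file round-trips through ``read_claims``.
    """
    rows = []
    any_labels = any(r.deducted is not None for r in claims.records)
    for rec in claims.records:
        for item, fee in rec.fees.items():
            row = {
                "case_id": rec.case_id,
                "drg": rec.drg_code,
                "year": rec.year,
                "item": item,
                "fee": repr(fee),
            }
            if any_labels:
                if rec.deducted is not None and item in rec.deducted:
                    row["deducted"] = int(rec.deducted[item])
                else:
                    row["deducted"] = ""
            rows.append(row)
    cols = list(CLAIMS_COLUMNS) + (["deducted"] if any_labels else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _model_to_dict(model: NormModel) -> dict:
    return {
        "drg_code": model.drg_code,
        "clamp_eps": model.clamp_eps,
        "items": {
            it.item_id: {
                "delta": it.delta,
                "se": it.se,
                "n_obs": it.n_obs,
                "min": model.bounds[it.item_id][0],
                "max": model.bounds[it.item_id][1],
            }
            for it in model.items
        },
        "bounds_extra": {
            "degenerate": sorted(model.bounds.degenerate),
            "unobserved": list(model.bounds.unobserved),
            "all_bounds": {
                i: list(model.bounds[i]) for i in model.bounds.bounds
            },
        },
        "calibration": {
            "tol": model.convergence.tol,
            "max_iter": model.convergence.max_iter,
            "iterations": model.convergence.iterations,
            "max_update_at_exit": model.convergence.max_update_at_exit,
            "converged": model.convergence.converged,
            "centered": True,
        },
    }


def _model_from_dict(d: dict) -> NormModel:
    try:
        cal = d["calibration"]
        bounds = NormalizationBounds(
            bounds={
                i: tuple(v) for i, v in d["bounds_extra"]["all_bounds"].items()
            },
            degenerate=frozenset(d["bounds_extra"]["degenerate"]),
            unobserved=tuple(d["bounds_extra"]["unobserved"]),
        )
        items = [
            ItemCalibration(
                item_id=i,
                delta=float(v["delta"]),
                se=float(v["se"]),
                n_obs=int(v["n_obs"]),
            )
            for i, v in d["items"].items()
        ]
        report = ConvergenceReport(
            iterations=int(cal["iterations"]),
            max_update_at_exit=float(cal["max_update_at_exit"]),
            converged=bool(cal["converged"]),
            tol=float(cal["tol"]),
            max_iter=int(cal["max_iter"]),
        )
        return NormModel(
            drg_code=d["drg_code"],
            bounds=bounds,
            items=items,
            convergence=report,
            clamp_eps=float(d["clamp_eps"]),
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"model entry malformed or truncated: {exc}")


def write_norm_models(
    models: Mapping[str, NormModel],
    schema: FeeItemSchema,
    path: str | Path,
) -> None:
    """Serialize calibrated models (one per DRG) plus the fee schema."""
    doc = {
        "format": MODEL_FORMAT,
        "schema": schema.to_dict(),
        "models": {drg: _model_to_dict(m) for drg, m in models.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_norm_models(
    path: str | Path,
) -> tuple[dict[str, NormModel], FeeItemSchema]:
    """Load models written by ``write_norm_models``.

    Raises ``ModelFormatError`` on truncation, missing fields, or a
    format-version mismatch — never a silent partial load.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})")
    if doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(
            f"{path}: expected format {MODEL_FORMAT!r}, "
            f"got {doc.get('format')!r}"
        )
    for key in ("schema", "models"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level field {key!r}")
    schema = FeeItemSchema.from_dict(doc["schema"])
    models = {drg: _model_from_dict(d) for drg, d in doc["models"].items()}
    return models, schema
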