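"""Standardized residual Z-scores, person fit, and up-coding flags.

For each observed cell of a scored case, the standardized residual

    Z_ni = (O_ni - E_ni) / sqrt(E_ni (1 - E_ni))

measures how far the claimed (normalized) fee sits above or below the
model expectation.  A cell with Z above the detection threshold
(default 2.0, roughly the 5% one-tail criterion for small samples)
flags the item as probably up-coded.  The outfit mean square — the
unweighted mean of squared residuals over a case's observed items —
summarizes person fit; it is reported but plays no part in flagging.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np

from .claims import ClaimRecord, ClaimSet, normalized_observations
from .rasch import AbilityEstimate, NormModel, estimate_ability, expected_score

DEFAULT_THRESHOLD = 2.0
SIDES = ("upper", "two")


@dataclass(frozen=True)
class ResidualCell:
    """One observed item of a scored case."""

    item_id: str
    O: float
    E: float
    var: float
    z: float
    raw_fee: float


@dataclass
class CaseScore:
    """Full per-case scoring result.

    ``status`` is "scored" for cases with at least one modelable item
    and "unscorable" otherwise (all fees missing on modeled items).
    ``flagged_items`` contains exactly the items whose Z exceeds the
    threshold on the configured side; ``case_flagged`` is true iff any
    item is flagged.
    """

    case_id: str
    drg_code: str
    year: int
    ability: AbilityEstimate | None
    cells: list[ResidualCell]
    outfit_mnsq: float | None
    flagged_items: frozenset[str]
    case_flagged: bool
    threshold: float = DEFAULT_THRESHOLD
    side: str = "upper"
    status: str = "scored"

    def max_z(self) -> float | None:
        if not self.cells:
            return None
        return max(c.z for c in self.cells)

    def z_by_item(self) -> dict[str, float]:
        return {c.item_id: c.z for c in self.cells}


def residual_z(o: float, e: float) -> float:
    """Standardized residual (O - E)/sqrt(E(1 - E)); requires 0 < E < 1."""
    if not 0.0 < e < 1.0:
        raise ValueError(f"expected score must be in (0, 1), got {e}")
    return (o - e) / math.sqrt(e * (1.0 - e))


def outfit_mnsq(cells: Iterable[ResidualCell]) -> float:
    """Outfit mean square: mean of z^2 over a case's observed cells."""
    zs = [c.z for c in cells]
    if not zs:
        raise ValueError("outfit requires at least one observed cell")
    return float(np.mean(np.square(zs)))


def flag_items(
    cells: Iterable[ResidualCell],
    threshold: float = DEFAULT_THRESHOLD,
    side: str = "upper",
) -> frozenset[str]:
    """Items whose residual exceeds the threshold.

    ``upper`` flags z > threshold (the up-coding direction); ``two``
    flags |z| > threshold.  The inequality is strict.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if side == "upper":
        return frozenset(c.item_id for c in cells if c.z > threshold)
    return frozenset(c.item_id for c in cells if abs(c.z) > threshold)


def score_case(
    record: ClaimRecord,
    model: NormModel,
    threshold: float = DEFAULT_THRESHOLD,
    side: str = "upper",
) -> CaseScore:
    """Score one case against its DRG's calibrated reference model.

    Normalizes the case's positive fees with the norm-group bounds,
    estimates ability from the observed items only, and fills residual
    cells.  A case with no observed modelable item yields an explicit
    unscorable result rather than an exception.
    """
    if record.drg_code != model.drg_code:
        raise ValueError(
            f"case {record.case_id} has DRG {record.drg_code}, model is "
            f"for {model.drg_code}"
        )
    deltas = model.deltas()
    obs = {
        i: x
        for i, x in normalized_observations(
            record, model.bounds, model.clamp_eps
        ).items()
        if i in deltas
    }
    if not obs:
        return CaseScore(
            case_id=record.case_id,
            drg_code=record.drg_code,
            year=record.year,
            ability=None,
            cells=[],
            outfit_mnsq=None,
            flagged_items=frozenset(),
            case_flagged=False,
            threshold=threshold,
            side=side,
            status="unscorable",
        )
    ability = estimate_ability(obs, deltas)
    cells: list[ResidualCell] = []
    for item, o in obs.items():
        e = float(expected_score(ability.theta, deltas[item]))
        cells.append(
            ResidualCell(
                item_id=item,
                O=o,
                E=e,
                var=e * (1.0 - e),
                z=residual_z(o, e),
                raw_fee=record.fees[item],
            )
        )
    flags = flag_items(cells, threshold, side)
    return CaseScore(
        case_id=record.case_id,
        drg_code=record.drg_code,
        year=record.year,
        ability=ability,
        cells=cells,
        outfit_mnsq=outfit_mnsq(cells),
        flagged_items=flags,
        case_flagged=bool(flags),
        threshold=threshold,
        side=side,
    )


@dataclass
class ScoringResult:
    """Batch scoring output with an audit trail of non-scored cases."""

    scores: list[CaseScore]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def scored(self) -> list[CaseScore]:
        return [s for s in self.scores if s.status == "scored"]

    def unscorable(self) -> list[CaseScore]:
        return [s for s in self.scores if s.status == "unscorable"]

    def n_cells(self) -> int:
        return sum(len(s.cells) for s in self.scores)


def score_claimset(
    claims: ClaimSet,
    models: Mapping[str, NormModel],
    threshold: float = DEFAULT_THRESHOLD,
    side: str = "upper",
) -> ScoringResult:
    """Score every case in a claim set against its DRG's model.

    Cases whose DRG has no model are reported in ``skipped`` with a
    reason rather than raising; unscorable cases (all items missing)
    appear in the scores with status "unscorable".
    """
    result = ScoringResult(scores=[])
    for rec in claims.records:
        model = models.get(rec.drg_code)
        if model is None:
            result.skipped.append((rec.case_id, f"no model for DRG {rec.drg_code}"))
            continue
        result.scores.append(score_case(rec, model, threshold, side))
    return result


# ---------------------------------------------------------------------------
# serialization — case scores round-trip through JSON and flatten to CSV

def case_score_to_dict(score: CaseScore) -> dict:
    d = {
        "case_id": score.case_id,
        "drg_code": score.drg_code,
        "year": score.year,
        "status": score.status,
        "threshold": score.threshold,
        "side": score.side,
        "outfit_mnsq": score.outfit_mnsq,
        "case_flagged": score.case_flagged,
        "flagged_items": sorted(score.flagged_items),
        "ability": None if score.ability is None else asdict(score.ability),
        "cells": [asdict(c) for c in score.cells],
    }
    return d


def case_score_from_dict(d: dict) -> CaseScore:
    ability = None
    if d["ability"] is not None:
        ability = AbilityEstimate(**d["ability"])
    return CaseScore(
        case_id=d["case_id"],
        drg_code=d["drg_code"],
        year=int(d["year"]),
        ability=ability,
        cells=[ResidualCell(**c) for c in d["cells"]],
        outfit_mnsq=d["outfit_mnsq"],
        flagged_items=frozenset(d["flagged_items"]),
        case_flagged=bool(d["case_flagged"]),
        threshold=float(d["threshold"]),
        side=d["side"],
        status=d["status"],
    )


def write_case_scores(scores: Iterable[CaseScore], path) -> None:
    payload = {
        "format": "drgrasch-case-scores/1",
        "scores": [case_score_to_dict(s) for s in scores],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_case_scores(path) -> list[CaseScore]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "drgrasch-case-scores/1":
        raise ValueError(f"{path}: not a drgrasch case-score file")
    return [case_score_from_dict(d) for d in payload["scores"]]


def case_scores_to_frame(scores: Iterable[CaseScore]):
    """Flat per-cell table (case_id, item, O, E, var, z, flagged)."""
    import pandas as pd

    rows = []
    for s in scores:
        for c in s.cells:
            rows.append(
                {
                    "case_id": s.case_id,
                    "drg": s.drg_code,
                    "year": s.year,
                    "item": c.item_id,
                    "fee": c.raw_fee,
                    "O": c.O,
                    "E": c.E,
                    "var": c.var,
                    "z": c.z,
                    "flagged": c.item_id in s.flagged_items,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "drg", "year", "item", "fee",
            "O", "E", "var", "z", "flagged",
        ],
    )
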