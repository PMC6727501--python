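"""Claim records, claim sets, and min-max fee normalization.

A claim set groups discharge cases by DRG code.  Each case carries a map
of fee-item amounts in an arbitrary currency; a zero or absent fee means
the case had no expenditure on that item and is treated as *missing*
throughout — zero fees never enter normalization bounds, calibration or
residuals.  Normalization rescales each observed fee to the unit
interval against the minimum and maximum fee observed on that item in
the norm (reference) group of the same DRG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .schema import FeeItemSchema

#: Symmetric clamp applied to normalized fees.  The raw min-max transform
#: attains exactly 0 and 1 at the group extremes, which makes logistic
#: likelihood contributions unbounded; the clamp is the standard
#: extreme-score adjustment that keeps every estimate finite.
CLAMP_EPS = 0.005

ROLES = ("norm", "experimental")


class ClaimsValidationError(ValueError):
    """Raised when claim data violates the schema or value constraints.

    ``errors`` lists every individual problem (with input line numbers
    when the data came from a file).
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid claims data:\n  " + "\n  ".join(self.errors)
        )


@dataclass
class ClaimRecord:
    """One discharge case: fees per item and optional audit labels.

    ``fees`` maps item_id -> claimed amount (>= 0; zero means missing).
    ``deducted`` optionally maps item_id -> whether the insurer removed
    that item from reimbursement after audit.
    """

    case_id: str
    drg_code: str
    year: int
    fees: dict[str, float]
    deducted: dict[str, bool] | None = None

    def observed_items(self) -> list[str]:
        """Items with a positive fee — the cells that enter the model."""
        return [i for i, f in self.fees.items() if f > 0]


@dataclass
class ClaimSet:
    """A schema-consistent collection of claim records.

    ``role`` distinguishes the norm (reference) group used to calibrate
    item difficulties from the experimental group that gets scored.
    """

    schema: FeeItemSchema
    records: list[ClaimRecord] = field(default_factory=list)
    role: str = "norm"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        errors: list[str] = []
        for rec in self.records:
            for item, fee in rec.fees.items():
                if item not in self.schema:
                    errors.append(
                        f"case {rec.case_id}: unknown item code {item!r}"
                    )
                if fee < 0:
                    errors.append(
                        f"case {rec.case_id}: negative fee {fee} on {item}"
                    )
            if rec.deducted is not None:
                for item in rec.deducted:
                    if item not in self.schema:
                        errors.append(
                            f"case {rec.case_id}: deduction label on "
                            f"unknown item {item!r}"
                        )
        if errors:
            raise ClaimsValidationError(errors)

    def __len__(self) -> int:
        return len(self.records)

    def drg_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.drg_code, None)
        return list(seen)

    def by_drg(self) -> dict[str, list[ClaimRecord]]:
        groups: dict[str, list[ClaimRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.drg_code, []).append(rec)
        return groups

    def for_drg(self, drg_code: str) -> list[ClaimRecord]:
        return [r for r in self.records if r.drg_code == drg_code]

    def labels(self) -> dict[str, dict[str, bool]]:
        """Per-case deduction labels, for cases that carry them."""
        return {
            r.case_id: dict(r.deducted)
            for r in self.records
            if r.deducted is not None
        }


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-item min/max fees observed in the norm group of one DRG.

    Items whose observed fees are all equal are *degenerate*: they carry
    no within-group variation and are excluded from modeling.  Items
    never observed are simply absent.
    """

    bounds: dict[str, tuple[float, float]]
    degenerate: frozenset[str] = frozenset()
    unobserved: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for item, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"item {item}: min {lo} > max {hi}")

    def usable_items(self) -> list[str]:
        """Items with non-degenerate bounds, in insertion order."""
        return [i for i in self.bounds if i not in self.degenerate]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.bounds

    def __getitem__(self, item_id: str) -> tuple[float, float]:
        return self.bounds[item_id]


def compute_bounds(
    norm: ClaimSet, drg_code: str, items: Iterable[str] | None = None
) -> NormalizationBounds:
    """Min-max normalization bounds from the norm group of one DRG.

    Only positive (non-missing) fees contribute.  Items with no
    observations are dropped with a warning; items whose fees are all
    equal are flagged degenerate and excluded from modeling downstream.

    Requires at least two cases for the DRG.
    """
    records = norm.for_drg(drg_code)
    if len(records) < 2:
        raise ClaimsValidationError(
            [
                f"DRG {drg_code}: need at least 2 norm cases to compute "
                f"bounds, got {len(records)}"
            ]
        )
    if items is None:
        items = norm.schema.item_ids
    bounds: dict[str, tuple[float, float]] = {}
    degenerate: set[str] = set()
    unobserved: list[str] = []
    for item in items:
        fees = [r.fees[item] for r in records if r.fees.get(item, 0.0) > 0]
        if not fees:
            unobserved.append(item)
            continue
        lo, hi = min(fees), max(fees)
        bounds[item] = (lo, hi)
        if lo == hi:
            degenerate.add(item)
    if unobserved:
        warnings.warn(
            f"DRG {drg_code}: items never observed in norm group, "
            f"dropped from bounds: {unobserved}",
            stacklevel=2,
        )
    return NormalizationBounds(
        bounds=bounds,
        degenerate=frozenset(degenerate),
        unobserved=tuple(unobserved),
    )


def normalize_fee(
    fee: float,
    lo: float,
    hi: float,
    eps: float = CLAMP_EPS,
) -> float:
    """Min-max rescale a fee to (0, 1), clamped to [eps, 1 - eps].

    The norm-group minimum maps to ``eps`` and the maximum to
    ``1 - eps``; fees outside the norm range are clamped.  Monotone
    non-decreasing in ``fee``.
    """
    if hi <= lo:
        raise ValueError(
            f"degenerate bounds (min {lo} >= max {hi}); item should have "
            "been excluded from modeling"
        )
    x = (fee - lo) / (hi - lo)
    return min(max(x, eps), 1.0 - eps)


def normalized_observations(
    record: ClaimRecord,
    bounds: NormalizationBounds,
    eps: float = CLAMP_EPS,
) -> dict[str, float]:
    """Normalized scores for a case's observed, modelable items.

    Skips missing (zero/absent) fees, items without bounds, and
    degenerate items.
    """
    usable = set(bounds.usable_items())
    obs: dict[str, float] = {}
    for item in record.observed_items():
        if item in usable:
            lo, hi = bounds[item]
            obs[item] = normalize_fee(record.fees[item], lo, hi, eps)
    return obs


def records_to_matrix(
    records: list[ClaimRecord],
    bounds: NormalizationBounds,
    eps: float = CLAMP_EPS,
):
    """Pivot records into a cases x items matrix of normalized scores.

    Missing cells are NaN.  Returns ``(matrix, case_ids, item_ids)``;
    the item order is the bounds' usable-item order.
    """
    import numpy as np

    item_ids = bounds.usable_items()
    col = {item: j for j, item in enumerate(item_ids)}
    mat = np.full((len(records), len(item_ids)), np.nan)
    for i, rec in enumerate(records):
        for item, x in normalized_observations(rec, bounds, eps).items():
            mat[i, col[item]] = x
    return mat, [r.case_id for r in records], item_ids


def labels_from_claimset(claims: ClaimSet) -> dict[str, dict[str, bool]]:
    """Deduction labels keyed by case id (convenience alias)."""
    return claims.labels()
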