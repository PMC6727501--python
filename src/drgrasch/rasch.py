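"""Continuous-response Rasch model: expected scores, ability estimation,
and joint (JMLE-style) item calibration.

The model treats each normalized fee ``O_ni`` in (0, 1) as a noisy
realization of the logistic expected score

    E_ni = exp(theta_n - delta_i) / (1 + exp(theta_n - delta_i)),

with quasi-binomial variance ``Var_ni = E_ni (1 - E_ni)``.  ``theta_n``
(case ability) summarizes a case's overall fee level within its DRG;
``delta_i`` (item difficulty) is high for items that are systematically
small or rare relative to the case total — on this scale a high fee is
an "easy" item.

Estimation uses Newton-Raphson on the score equations.  For a case with
observed items ``I_n`` the update is

    theta <- theta + sum_{i in I_n} (O_ni - E_ni) / sum_{i in I_n} Var_ni,

whose fixed point satisfies the score condition sum(O - E) = 0; with a
single observed item this reduces to the textbook single-cell update.
Item difficulties are estimated by the mirrored step over cases and
re-centered to mean zero each sweep (the location of the logit scale is
otherwise unidentified).  Missing cells (zero fees) contribute nothing:
every sum runs over observed cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .claims import ClaimSet, NormalizationBounds, compute_bounds, records_to_matrix

__all__ = [
    "AbilityEstimate",
    "ItemCalibration",
    "ConvergenceReport",
    "NormModel",
    "expected_score",
    "cell_variance",
    "estimate_ability",
    "calibrate_items",
    "fit_norm_model",
]

#: Maximum Newton step, in logits, taken in one iteration.  Caps the
#: update so a poor start cannot overshoot into the flat tails of the
#: logistic where the variance (the Newton denominator) vanishes.
STEP_CAP = 1.0

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100


def expected_score(theta, delta):
    """Logistic expected score E = exp(theta - delta)/(1 + exp(theta - delta)).

    Overflow-safe; accepts scalars or arrays (broadcasting).  Strictly
    increasing in ``theta`` and decreasing in ``delta``.
    """
    return expit(np.asarray(theta) - np.asarray(delta))


def cell_variance(e):
    """Model variance of one cell, Var = E (1 - E); maximal 0.25 at E = 0.5."""
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise ValueError("expected score must lie strictly inside (0, 1)")
    return e * (1.0 - e)


@dataclass(frozen=True)
class AbilityEstimate:
    """A case's estimated ability on the logit scale.

    ``se = 1/sqrt(sum Var_i)`` at the estimate; ``converged`` is False
    when the Newton iteration hit the iteration cap first.
    """

    theta: float
    se: float
    n_items_used: int
    converged: bool


@dataclass(frozen=True)
class ItemCalibration:
    """One item's calibrated difficulty (logits) with its standard error."""

    item_id: str
    delta: float
    se: float
    n_obs: int


@dataclass(frozen=True)
class ConvergenceReport:
    iterations: int
    max_update_at_exit: float
    converged: bool
    tol: float
    max_iter: int


@dataclass
class NormModel:
    """Calibrated reference model for one DRG.

    Bundles the normalization bounds of the norm group with the item
    difficulties estimated on it, so a new case can be scored by
    normalizing its fees against the same reference.
    """

    drg_code: str
    bounds: NormalizationBounds
    items: list[ItemCalibration]
    convergence: ConvergenceReport
    clamp_eps: float = 0.005

    def __post_init__(self) -> None:
        if self.items:
            mean = float(np.mean([it.delta for it in self.items]))
            if abs(mean) > 1e-8:
                raise ValueError(
                    f"item difficulties must be centered (mean {mean:.3g})"
                )
        for it in self.items:
            if it.item_id not in self.bounds:
                raise ValueError(f"calibrated item {it.item_id} has no bounds")

    def deltas(self) -> dict[str, float]:
        return {it.item_id: it.delta for it in self.items}

    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]


def estimate_ability(
    obs: Mapping[str, float],
    deltas: Mapping[str, float],
    start: float = 0.0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    step_cap: float = STEP_CAP,
) -> AbilityEstimate:
    """Estimate a case's ability from its observed normalized scores.

    Solves the score condition ``sum_i (O_i - E_i(theta)) = 0`` over the
    observed items only by capped Newton-Raphson.  Missing items simply
    do not appear in ``obs``.  With one item the closed form is
    ``theta = delta + logit(O)``.

    Raises ``ValueError`` on empty observations, observations outside
    (0, 1), or items without a calibrated difficulty.
    """
    if not obs:
        raise ValueError("cannot estimate ability from zero observed items")
    unknown = [i for i in obs if i not in deltas]
    if unknown:
        raise ValueError(f"items without calibrated difficulty: {unknown}")
    o = np.array([obs[i] for i in obs], dtype=float)
    d = np.array([deltas[i] for i in obs], dtype=float)
    if np.any(o <= 0.0) or np.any(o >= 1.0):
        raise ValueError("observations must lie strictly inside (0, 1)")

    theta = float(start)
    converged = False
    var = np.full_like(o, 0.25)
    for _ in range(max_iter):
        e = expit(theta - d)
        var = e * (1.0 - e)
        step = float(np.sum(o - e) / np.sum(var))
        step = float(np.clip(step, -step_cap, step_cap))
        theta += step
        if abs(step) < tol:
            converged = True
            break
    e = expit(theta - d)
    var = e * (1.0 - e)
    se = float(1.0 / np.sqrt(np.sum(var)))
    return AbilityEstimate(
        theta=theta, se=se, n_items_used=len(o), converged=converged
    )


def _check_connected(mask: np.ndarray, item_ids: Sequence[str]) -> None:
    """Items must be linked through shared cases; otherwise the relative
    difficulty of a disconnected item is unidentified."""
    n_items = mask.shape[1]
    parent = list(range(n_items))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for row in mask:
        cols = np.flatnonzero(row)
        for j in cols[1:]:
            ra, rb = find(int(cols[0])), find(int(j))
            if ra != rb:
                parent[rb] = ra
    roots = {find(j) for j in range(n_items)}
    if len(roots) > 1:
        main = max(roots, key=lambda r: sum(find(j) == r for j in range(n_items)))
        orphans = [item_ids[j] for j in range(n_items) if find(j) != main]
        raise ValueError(
            f"disconnected item-case structure: items {orphans} share no "
            "case with the rest and cannot be placed on a common scale"
        )


def calibrate_items(
    matrix: np.ndarray,
    item_ids: Sequence[str],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    step_cap: float = STEP_CAP,
) -> tuple[list[ItemCalibration], np.ndarray, ConvergenceReport]:
    """Jointly calibrate item difficulties on a norm matrix.

    ``matrix`` is cases x items of normalized scores in (0, 1) with NaN
    for missing cells.  Alternates (a) a full ability solve for every
    case given current difficulties, (b) one mirrored Newton step for
    every difficulty given the abilities, (c) re-centering difficulties
    to mean zero, until the largest parameter update in a sweep falls
    below ``tol``.  Deterministic given input order.

    Returns ``(calibrations, thetas, report)`` where ``thetas`` are the
    final norm-group abilities (by row).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (cases x items)")
    n_cases, n_items = x.shape
    if n_items != len(item_ids):
        raise ValueError("item_ids length does not match matrix columns")
    if n_cases < 2 or n_items < 2:
        raise ValueError(
            f"calibration needs >= 2 cases and >= 2 items, got "
            f"{n_cases} x {n_items}"
        )
    mask = ~np.isnan(x)
    obs_per_item = mask.sum(axis=0)
    thin = [item_ids[j] for j in np.flatnonzero(obs_per_item < 2)]
    if thin:
        raise ValueError(f"items observed by fewer than 2 cases: {thin}")
    if np.any(mask.sum(axis=1) < 1):
        bad = int(np.flatnonzero(mask.sum(axis=1) < 1)[0])
        raise ValueError(f"case at row {bad} observes no items")
    inside = x[mask]
    if np.any(inside <= 0.0) or np.any(inside >= 1.0):
        raise ValueError("normalized scores must lie strictly inside (0, 1)")
    _check_connected(mask, item_ids)

    xz = np.where(mask, x, 0.0)
    theta = np.zeros(n_cases)
    delta = np.zeros(n_items)
    max_update = np.inf
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        # (a) full ability solve, vectorized over cases
        for _ in range(max_iter):
            e = expit(theta[:, None] - delta[None, :])
            var = np.where(mask, e * (1.0 - e), 0.0)
            resid = np.where(mask, xz - e, 0.0)
            step = resid.sum(axis=1) / var.sum(axis=1)
            np.clip(step, -step_cap, step_cap, out=step)
            theta += step
            if np.max(np.abs(step)) < tol:
                break
        # (b) one mirrored Newton step per item
        e = expit(theta[:, None] - delta[None, :])
        var = np.where(mask, e * (1.0 - e), 0.0)
        resid = np.where(mask, xz - e, 0.0)
        dstep = -resid.sum(axis=0) / var.sum(axis=0)
        np.clip(dstep, -step_cap, step_cap, out=dstep)
        delta += dstep
        # (c) identifiability: difficulties sum to zero
        shift = delta.mean()
        delta -= shift
        theta -= shift  # keep theta - delta invariant across sweeps
        max_update = float(np.max(np.abs(dstep)))
        if max_update < tol:
            break
    converged = max_update < tol

    e = expit(theta[:, None] - delta[None, :])
    var = np.where(mask, e * (1.0 - e), 0.0)
    se = 1.0 / np.sqrt(var.sum(axis=0))
    cal = [
        ItemCalibration(
            item_id=item_ids[j],
            delta=float(delta[j] - delta.mean()),
            se=float(se[j]),
            n_obs=int(obs_per_item[j]),
        )
        for j in range(n_items)
    ]
    report = ConvergenceReport(
        iterations=sweeps,
        max_update_at_exit=max_update,
        converged=converged,
        tol=tol,
        max_iter=max_iter,
    )
    return cal, theta, report


def fit_norm_model(
    norm: ClaimSet,
    drg_code: str,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    clamp_eps: float = 0.005,
) -> NormModel:
    """Calibrate a reference model for one DRG from a norm claim set.

    Computes normalization bounds on the norm group, pivots its records
    into a normalized matrix (zero fees missing), and runs the joint
    calibration.  Non-convergence yields a model with a warning, not an
    exception, so a long calibration batch is never lost to one DRG.
    """
    import warnings

    bounds = compute_bounds(norm, drg_code)
    records = norm.for_drg(drg_code)
    matrix, _, item_ids = records_to_matrix(records, bounds, clamp_eps)
    cal, _, report = calibrate_items(matrix, item_ids, tol, max_iter)
    if not report.converged:
        warnings.warn(
            f"DRG {drg_code}: calibration stopped after {report.iterations} "
            f"sweeps with max update {report.max_update_at_exit:.2e} > "
            f"tol {tol}",
            stacklevel=2,
        )
    return NormModel(
        drg_code=drg_code,
        bounds=bounds,
        items=cal,
        convergence=report,
        clamp_eps=clamp_eps,
    )


def closed_form_single_item(o: float, delta: float) -> float:
    """Single-item ability in closed form: theta = delta + logit(O)."""
    return float(delta + logit(o))
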