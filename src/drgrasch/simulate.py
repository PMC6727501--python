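"""Synthetic DRG claim generator with known ground truth.

Emulates the statistical structure the detector assumes: within one
DRG, case abilities theta_n and item difficulties delta_i are drawn
from normal distributions; each observed cell's normalized fee is a
Beta draw with mean E_ni = logistic(theta_n - delta_i) and precision m
(shape parameters E*m and (1-E)*m), mapped to currency through a fixed
per-item scale; cells go missing independently.  Up-coding is injected
by shifting selected cells upward on the normalized scale, and the
injected (case, item) pairs are exported as the "deducted" audit
labels — so the whole pipeline, calibration through evaluation, runs
against a known truth.

The Beta noise has variance E(1-E)/(1+m), deliberately *smaller* than
the model's nominal quasi-variance E(1-E): normalized fees are a single
bounded measurement, not a binomial proportion.  Null residuals are
therefore under-dispersed and the nominal z > 2 false-flag rate is
conservative (well below 2.5% per cell).

Randomness is split into one child stream per purpose (difficulties,
abilities, noise, missingness, injection), all spawned from the master
seed, so toggling injection never perturbs the base data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .claims import CLAMP_EPS, ClaimRecord, ClaimSet
from .rasch import expected_score
from .schema import FeeItemSchema, default_schema


class SimConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid simulation config:\n  " + "\n  ".join(self.errors)
        )


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults mirror the study design the detector targets: a norm group
    of 300 undeducted cases and an experimental group of 194 audited
    cases on a 17-item fee schema, every experimental case up-coded on
    one item (audited cases had at least one item deducted), with a
    shift of 0.4 on the normalized fee scale.
    """

    n_norm: int = 300
    n_exp: int = 194
    n_items: int = 17
    sigma_delta: float = 1.0   # sd of item difficulties (logits)
    sigma_theta: float = 1.0   # sd of case abilities (logits)
    precision: float = 9.0     # Beta precision m; Var = E(1-E)/(1+m)
    p_miss: float = 0.1        # per-cell missingness probability
    upcode_rate: float = 1.0   # fraction of experimental cases up-coded
    upcode_items_per_case: int = 1
    upcode_shift: float = 0.4  # added on the normalized (0,1) scale
    fee_scale: float = 25000.0  # currency per unit of normalized fee
    drg_code: str = "DRG-SYN"
    year_split: float = 0.5    # fraction of cases labeled year 2015
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_norm < 2:
            errs.append(f"n_norm must be >= 2, got {self.n_norm}")
        if self.n_exp < 2:
            errs.append(f"n_exp must be >= 2, got {self.n_exp}")
        if self.n_items < 2:
            errs.append(f"n_items must be >= 2, got {self.n_items}")
        if not 0.0 <= self.p_miss <= 1.0:
            errs.append(f"p_miss must be in [0,1], got {self.p_miss}")
        if not 0.0 <= self.upcode_rate <= 1.0:
            errs.append(f"upcode_rate must be in [0,1], got {self.upcode_rate}")
        if not 0.0 < self.upcode_shift <= 1.0:
            errs.append(
                f"upcode_shift must be in (0,1], got {self.upcode_shift}"
            )
        if self.precision <= 0:
            errs.append(f"precision must be > 0, got {self.precision}")
        if self.upcode_items_per_case < 1:
            errs.append("upcode_items_per_case must be >= 1")
        if self.fee_scale <= 0:
            errs.append(f"fee_scale must be > 0, got {self.fee_scale}")
        if not 0.0 <= self.year_split <= 1.0:
            errs.append(f"year_split must be in [0,1], got {self.year_split}")
        if errs:
            raise SimConfigError(errs)

    def make_schema(self) -> FeeItemSchema:
        base = default_schema()
        if self.n_items == len(base):
            return base
        if self.n_items < len(base):
            return FeeItemSchema(base.items[: self.n_items])
        extra = tuple(
            base.items[0].__class__(f"GEN{k:02d}", f"generic fee {k}", "other")
            for k in range(self.n_items - len(base))
        )
        return FeeItemSchema(base.items + extra)


@dataclass
class SimTruth:
    """Ground truth behind a simulated claim set."""

    deltas: dict[str, float]
    thetas: dict[str, float]
    missing: set[tuple[str, str]]
    upcoded: set[tuple[str, str]] = field(default_factory=set)
    pre_shift: dict[tuple[str, str], float] = field(default_factory=dict)

    def delta_vector(self, item_ids) -> np.ndarray:
        return np.array([self.deltas[i] for i in item_ids])


# stream indices spawned from the master seed
_STREAMS = {
    "deltas": 0,
    "norm_theta": 1,
    "norm_noise": 2,
    "norm_miss": 3,
    "exp_theta": 4,
    "exp_noise": 5,
    "exp_miss": 6,
    "inject": 7,
}


def _rng(config: SimConfig, purpose: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[purpose]])


def _draw_deltas(config: SimConfig, item_ids) -> dict[str, float]:
    raw = _rng(config, "deltas").normal(0.0, config.sigma_delta, len(item_ids))
    raw -= raw.mean()  # generated difficulties honor the centering convention
    return dict(zip(item_ids, raw.tolist()))


def simulate_claimset(
    config: SimConfig, role: str = "norm"
) -> tuple[ClaimSet, SimTruth]:
    """Generate one claim set (norm or experimental) with its truth.

    Both roles share the same item difficulties for a given seed, so a
    norm set and an experimental set from the same config belong to the
    same synthetic DRG.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    if role not in ("norm", "experimental"):
        raise ValueError(f"role must be norm or experimental, got {role!r}")
    schema = config.make_schema()
    item_ids = list(schema.item_ids)
    deltas = _draw_deltas(config, item_ids)
    n = config.n_norm if role == "norm" else config.n_exp
    prefix = "N" if role == "norm" else "E"

    theta = _rng(config, f"{'norm' if role == 'norm' else 'exp'}_theta").normal(
        0.0, config.sigma_theta, n
    )
    noise = _rng(config, f"{'norm' if role == 'norm' else 'exp'}_noise")
    miss_rng = _rng(config, f"{'norm' if role == 'norm' else 'exp'}_miss")

    d = np.array([deltas[i] for i in item_ids])
    e = np.asarray(expected_score(theta[:, None], d[None, :]))
    m = config.precision
    x = noise.beta(e * m, (1.0 - e) * m)
    miss = miss_rng.random((n, len(item_ids))) < config.p_miss

    records: list[ClaimRecord] = []
    missing_pairs: set[tuple[str, str]] = set()
    thetas: dict[str, float] = {}
    n_first_year = int(round(n * config.year_split))
    for row in range(n):
        case_id = f"{prefix}{row + 1:04d}"
        thetas[case_id] = float(theta[row])
        fees: dict[str, float] = {}
        deducted: dict[str, bool] | None = None
        for col, item in enumerate(item_ids):
            if miss[row, col]:
                missing_pairs.add((case_id, item))
                continue
            fees[item] = float(x[row, col]) * config.fee_scale
        if role == "experimental":
            deducted = {i: False for i in fees}
        records.append(
            ClaimRecord(
                case_id=case_id,
                drg_code=config.drg_code,
                year=2015 if row < n_first_year else 2016,
                fees=fees,
                deducted=deducted,
            )
        )
    if all(not r.fees for r in records):
        raise SimConfigError(
            ["no scorable cases: every cell is missing (p_miss too high)"]
        )
    truth = SimTruth(deltas=deltas, thetas=thetas, missing=missing_pairs)
    return ClaimSet(schema=schema, records=records, role=role), truth


def inject_upcoding(
    claims: ClaimSet, truth: SimTruth, config: SimConfig
) -> tuple[ClaimSet, SimTruth]:
    """Inject up-coding into an experimental claim set.

    Selects ``round(upcode_rate * n)`` cases; in each, shifts
    ``upcode_items_per_case`` randomly chosen observed cells upward by
    ``upcode_shift`` on the normalized scale (capped below 1), maps
    back to currency, and records the pair as deducted.  Returns new
    objects; the inputs are not mutated.
    """
    config.validate()
    if claims.role != "experimental":
        raise ValueError("up-coding is injected into experimental sets only")
    rng = _rng(config, "inject")
    n_cases = len(claims.records)
    n_pick = int(round(config.upcode_rate * n_cases))
    picked = set(rng.choice(n_cases, size=n_pick, replace=False).tolist())

    new_records: list[ClaimRecord] = []
    upcoded = set(truth.upcoded)
    pre_shift = dict(truth.pre_shift)
    cap = 1.0 - CLAMP_EPS
    for idx, rec in enumerate(claims.records):
        fees = dict(rec.fees)
        deducted = dict(rec.deducted) if rec.deducted is not None else {
            i: False for i in fees
        }
        if idx in picked and fees:
            items = sorted(fees)
            k = min(config.upcode_items_per_case, len(items))
            chosen = rng.choice(len(items), size=k, replace=False)
            for j in sorted(chosen.tolist()):
                item = items[j]
                x = fees[item] / config.fee_scale
                x_new = min(cap, x + config.upcode_shift)
                pre_shift[(rec.case_id, item)] = x
                fees[item] = x_new * config.fee_scale
                deducted[item] = True
                upcoded.add((rec.case_id, item))
        new_records.append(
            ClaimRecord(
                case_id=rec.case_id,
                drg_code=rec.drg_code,
                year=rec.year,
                fees=fees,
                deducted=deducted,
            )
        )
    new_truth = SimTruth(
        deltas=dict(truth.deltas),
        thetas=dict(truth.thetas),
        missing=set(truth.missing),
        upcoded=upcoded,
        pre_shift=pre_shift,
    )
    return (
        ClaimSet(schema=claims.schema, records=new_records, role="experimental"),
        new_truth,
    )


def simulate_study(
    config: SimConfig,
) -> tuple[ClaimSet, SimTruth, ClaimSet, SimTruth]:
    """Generate a full study: a clean norm group and an up-coded
    experimental group on the same synthetic DRG.

    Returns ``(norm_set, norm_truth, exp_set, exp_truth)``.
    """
    norm_set, norm_truth = simulate_claimset(config, role="norm")
    exp_set, exp_truth = simulate_claimset(config, role="experimental")
    if config.upcode_rate > 0:
        exp_set, exp_truth = inject_upcoding(exp_set, exp_truth, config)
    return norm_set, norm_truth, exp_set, exp_truth


def truth_to_frame(truth: SimTruth):
    """Flatten the up-coding labels to a (case_id, item, upcoded) table."""
    import pandas as pd

    rows = [
        {"case_id": c, "item": i, "upcoded": 1} for c, i in sorted(truth.upcoded)
    ]
    return pd.DataFrame(rows, columns=["case_id", "item", "upcoded"])
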