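"""Evaluation of flags against audit labels: accuracy tables, Pearson
chi-square year comparisons, and ROC analysis.

The ground truth is the insurer's per-item deduction decision.  A case
counts as *correct* either in ``matched`` mode (at least one actually
deducted item was flagged) or in ``any`` mode (the case was flagged at
all, regardless of which item).  Year-stratified correct/incorrect
counts are compared by the uncorrected Pearson chi-square; ROC uses the
Mann-Whitney (rank) formulation of the AUC with the Hanley-McNeil
standard error for the test against the chance value 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

from .detection import CaseScore

MODES = ("matched", "any")


@dataclass(frozen=True)
class ConfusionCounts:
    correct: int
    incorrect: int

    def __post_init__(self) -> None:
        if self.correct < 0 or self.incorrect < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.correct + self.incorrect

    @property
    def rate(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("no evaluable cases")
        return self.correct / self.total


@dataclass
class EvalTable:
    """Stratified correct/incorrect counts with a homogeneity test.

    ``strata`` maps a stratum label (e.g. a year) to its counts;
    ``pooled`` sums them.  ``chi2``/``p`` test whether the correct rate
    is homogeneous across strata (omitted for a single stratum).
    """

    strata: dict[str, ConfusionCounts]
    pooled: ConfusionCounts
    chi2: float | None = None
    p: float | None = None
    mode: str = "matched"
    not_evaluable: int = 0

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "stratum": label,
                "correct": c.correct,
                "incorrect": c.incorrect,
                "total": c.total,
                "rate": c.rate,
            }
            for label, c in self.strata.items()
        ]
        rows.append(
            {
                "stratum": "pooled",
                "correct": self.pooled.correct,
                "incorrect": self.pooled.incorrect,
                "total": self.pooled.total,
                "rate": self.pooled.rate,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    se: float
    p_vs_half: float


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    No Yates continuity correction is applied.  Returns (statistic,
    two-sided tail p) with 1 degree of freedom.  All four marginals must
    be positive.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("all marginals of the 2x2 table must be positive")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2_dist.sf(stat, df=1))


def pearson_chi2_table(table: np.ndarray) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for an r x c contingency table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    n = t.sum()
    if np.any(rows <= 0):
        raise ValueError("all row marginals must be positive")
    if np.any(cols <= 0):
        # a column with no observations carries no heterogeneity at all
        return 0.0, 1.0
    expected = rows @ cols / n
    stat = float(np.sum((t - expected) ** 2 / expected))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, df=df))


def case_correct(
    score: CaseScore,
    labels: Mapping[str, bool],
    mode: str = "matched",
) -> bool | None:
    """Whether the flags agree with the audit outcome for one case.

    ``matched``: true iff at least one actually deducted item was
    flagged.  Returns None ("not evaluable") when the case has no
    deducted item, since there is nothing to match.  ``any``: true iff
    the case was flagged at all.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if labels is None:
        raise ValueError(f"case {score.case_id}: no audit labels")
    deducted = {i for i, v in labels.items() if v}
    if mode == "any":
        return score.case_flagged
    if not deducted:
        return None
    return bool(deducted & score.flagged_items)


def accuracy_table(
    scores: Sequence[CaseScore],
    labels: Mapping[str, Mapping[str, bool]],
    mode: str = "matched",
) -> EvalTable:
    """Year-stratified correct-rate table with a chi-square homogeneity test.

    Cases without labels or not evaluable in ``matched`` mode are
    excluded and counted in ``not_evaluable``.  With a single stratum
    the table is emitted without a test.
    """
    per_year: dict[str, list[bool]] = {}
    skipped = 0
    for s in scores:
        if s.status != "scored":
            skipped += 1
            continue
        lab = labels.get(s.case_id)
        if lab is None:
            skipped += 1
            continue
        verdict = case_correct(s, lab, mode)
        if verdict is None:
            skipped += 1
            continue
        per_year.setdefault(str(s.year), []).append(verdict)
    strata = {
        y: ConfusionCounts(sum(v), len(v) - sum(v))
        for y, v in sorted(per_year.items())
    }
    if not strata:
        raise ValueError("no evaluable cases")
    pooled = ConfusionCounts(
        sum(c.correct for c in strata.values()),
        sum(c.incorrect for c in strata.values()),
    )
    table = EvalTable(
        strata=strata, pooled=pooled, mode=mode, not_evaluable=skipped
    )
    if len(strata) >= 2:
        counts = np.array(
            [[c.correct, c.incorrect] for c in strata.values()], dtype=float
        )
        table.chi2, table.p = pearson_chi2_table(counts)
    return table


def category_table(
    scores: Sequence[CaseScore],
    labels: Mapping[str, Mapping[str, bool]],
    category_map: Mapping[str, str],
    categories: Sequence[str] = ("drug", "material", "examination"),
) -> dict[str, EvalTable]:
    """Per-category accuracy tables.

    For each case and category, the prediction is "any item in the
    category flagged" and the truth is "any item in the category
    deducted"; the case is correct when they agree.  Every labeled case
    is evaluable in every category, so the denominators equal the case
    counts per year.
    """
    for s in scores:
        for c in s.cells:
            if c.item_id not in category_map:
                raise ValueError(f"item {c.item_id} has no category mapping")
    out: dict[str, EvalTable] = {}
    for cat in categories:
        cat_items = {i for i, c in category_map.items() if c == cat}
        per_year: dict[str, list[bool]] = {}
        skipped = 0
        for s in scores:
            if s.status != "scored":
                skipped += 1
                continue
            lab = labels.get(s.case_id)
            if lab is None:
                skipped += 1
                continue
            flagged = bool(s.flagged_items & cat_items)
            deducted = any(lab.get(i, False) for i in cat_items)
            per_year.setdefault(str(s.year), []).append(flagged == deducted)
        strata = {
            y: ConfusionCounts(sum(v), len(v) - sum(v))
            for y, v in sorted(per_year.items())
        }
        if not strata:
            raise ValueError(f"category {cat}: no evaluable cases")
        pooled = ConfusionCounts(
            sum(c.correct for c in strata.values()),
            sum(c.incorrect for c in strata.values()),
        )
        table = EvalTable(
            strata=strata, pooled=pooled, mode="category", not_evaluable=skipped
        )
        if len(strata) >= 2:
            counts = np.array(
                [[c.correct, c.incorrect] for c in strata.values()],
                dtype=float,
            )
            table.chi2, table.p = pearson_chi2_table(counts)
        out[cat] = table
    return out


def auc_mann_whitney(
    scores: Sequence[float], labels: Sequence[bool]
) -> RocResult:
    """AUC by the Mann-Whitney rank statistic, with a test against 0.5.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg),
    computed from midranks.  The standard error uses the Hanley-McNeil
    exponential approximation; ``p_vs_half`` is the two-sided normal
    tail probability for AUC = 0.5.
    """
    y = np.asarray(labels, dtype=bool)
    x = np.asarray(scores, dtype=float)
    if y.shape != x.shape or x.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(x)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2.0 * norm_dist.sf(abs(auc - 0.5) / se))
    return RocResult(
        auc=float(auc), n_pos=n_pos, n_neg=n_neg, se=se, p_vs_half=p
    )


def roc_points(
    scores: Sequence[float], labels: Sequence[bool]
) -> "np.ndarray":
    """ROC curve points (FPR, TPR) at every distinct threshold,
    descending in threshold; includes the (0,0) and (1,1) endpoints."""
    y = np.asarray(labels, dtype=bool)
    x = np.asarray(scores, dtype=float)
    order = np.argsort(-x, kind="stable")
    y = y[order]
    x = x[order]
    distinct = np.r_[np.flatnonzero(np.diff(x)), y.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = tps / y.sum()
    fpr = fps / (~y).sum()
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def item_level_roc(
    scores: Sequence[CaseScore],
    labels: Mapping[str, Mapping[str, bool]],
) -> RocResult:
    """ROC of per-cell Z against per-item deduction labels.

    One observation per residual cell that carries a label; the score is
    the cell's Z, the outcome is whether the insurer deducted the item.
    """
    zs: list[float] = []
    ys: list[bool] = []
    for s in scores:
        lab = labels.get(s.case_id)
        if lab is None:
            continue
        for c in s.cells:
            if c.item_id in lab:
                zs.append(c.z)
                ys.append(bool(lab[c.item_id]))
    return auc_mann_whitney(zs, ys)


def category_roc(
    scores: Sequence[CaseScore],
    labels: Mapping[str, Mapping[str, bool]],
    category_map: Mapping[str, str],
    categories: Sequence[str] = ("drug", "material", "examination"),
    by_year: bool = False,
) -> dict[str, RocResult]:
    """Case-level ROC per category: score = max Z over the category's
    observed items, truth = any deduction in the category.

    With ``by_year`` the keys become "<category>/<year>"."""
    out: dict[str, RocResult] = {}
    for cat in categories:
        cat_items = {i for i, c in category_map.items() if c == cat}
        buckets: dict[str, tuple[list[float], list[bool]]] = {}
        for s in scores:
            lab = labels.get(s.case_id)
            if lab is None or s.status != "scored":
                continue
            cat_cells = [c.z for c in s.cells if c.item_id in cat_items]
            if not cat_cells:
                continue
            key = f"{cat}/{s.year}" if by_year else cat
            xs, ys = buckets.setdefault(key, ([], []))
            xs.append(max(cat_cells))
            ys.append(any(lab.get(i, False) for i in cat_items))
        for key, (xs, ys) in buckets.items():
            out[key] = auc_mann_whitney(xs, ys)
    return out
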