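"""Diagnostic accuracy of the screen against the gold-standard diagnosis.

Positivity convention throughout: a screen is *positive* when the total
score is **at or below** the cutoff (lower IHDS totals mean worse
performance).  Sensitivity is therefore non-decreasing and specificity
non-increasing as the cutoff rises, and the ROC curve is traced by sweeping
the cutoff over the observed half-point grid.

Provided quantities: confusion tables per cutoff; sensitivity, specificity,
PPV, NPV and Youden's J = sensitivity + specificity - 1; the ROC curve with
trapezoidal AUC (equal to the tie-corrected Mann-Whitney statistic);
Youden-optimal cutoff selection; and the phi coefficient for 2x2
screen-vs-assessment agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "ROCPoint",
    "ROCCurve",
    "ScreenEvalError",
    "confusion_at_cutoff",
    "diagnostic_metrics",
    "roc",
    "optimal_cutoff",
    "agreement",
    "cutoff_table",
]


class ScreenEvalError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table: disease status (rows) x screen result (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ScreenEvalError(f"{name}={v!r} is not a valid count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionTable":
        return ConfusionTable(self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy summary of one cutoff; undefined fields are ``None``.

    A field is undefined when its denominator margin is empty (for example
    sensitivity with no diseased subjects); undefined values are reported
    as ``None`` rather than silent zeros.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    youden_j: Optional[float]


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> ConfusionTable:
    """Cross-tabulate disease labels against screen positivity at *cutoff*."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size == 0:
        raise ScreenEvalError("empty input")
    if s.shape != y.shape:
        raise ScreenEvalError(f"length mismatch: {s.size} scores, {y.size} labels")
    pos = s <= cutoff
    return ConfusionTable(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        fn=int(np.sum(~pos & y)),
        tn=int(np.sum(~pos & ~y)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostic_metrics(table: ConfusionTable) -> DiagnosticMetrics:
    sens = _ratio(table.tp, table.tp + table.fn)
    spec = _ratio(table.tn, table.tn + table.fp)
    ppv = _ratio(table.tp, table.tp + table.fp)
    npv = _ratio(table.tn, table.tn + table.fn)
    j = sens + spec - 1.0 if sens is not None and spec is not None else None
    return DiagnosticMetrics(sens, spec, ppv, npv, j)


@dataclass(frozen=True)
class ROCPoint:
    cutoff: float
    sensitivity: float
    fpr: float
    table: ConfusionTable


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[ROCPoint, ...]
    auc: float
    n_pos: int
    n_neg: int


def roc(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC curve over the observed cutoffs, plus the (0, 0) endpoint.

    One point per distinct observed score (used as a cutoff, positivity
    score <= cutoff); the degenerate all-negative operating point is
    prepended with cutoff -inf, and the all-positive point (1, 1) arises at
    the maximum observed score.  AUC is the trapezoidal area, which for
    this construction equals the tie-corrected Mann-Whitney statistic
    P(score_diseased < score_healthy) + 0.5 * P(equal).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.size == 0:
        raise ScreenEvalError("scores and labels must be equal-length, non-empty")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ScreenEvalError("both classes must be present for an ROC curve")

    cutoffs = [-math.inf, *np.unique(s)]
    points = []
    for c in cutoffs:
        if math.isinf(c):
            table = ConfusionTable(0, 0, n_pos, n_neg)
        else:
            table = confusion_at_cutoff(s, y, c)
        points.append(
            ROCPoint(
                cutoff=float(c),
                sensitivity=table.tp / n_pos,
                fpr=table.fp / n_neg,
                table=table,
            )
        )
    fprs = np.array([p.fpr for p in points])
    senss = np.array([p.sensitivity for p in points])
    auc = float(np.trapezoid(senss, fprs))
    return ROCCurve(points=tuple(points), auc=auc, n_pos=n_pos, n_neg=n_neg)


def optimal_cutoff(
    curve: ROCCurve | Iterable[tuple[float, DiagnosticMetrics]],
    criterion: str = "max_youden",
) -> tuple[float, DiagnosticMetrics]:
    """Cutoff maximising Youden's J; ties break toward the lower cutoff
    (fewer screen-positives).  Accepts an :class:`ROCCurve` or an iterable
    of ``(cutoff, DiagnosticMetrics)`` pairs (e.g. a published table).
    """
    if criterion != "max_youden":
        raise ScreenEvalError(f"unknown criterion {criterion!r}")
    if isinstance(curve, ROCCurve):
        items = [
            (p.cutoff, diagnostic_metrics(p.table))
            for p in curve.points
            if math.isfinite(p.cutoff)
        ]
    else:
        items = list(curve)
    items = [(c, m) for c, m in items if m.youden_j is not None]
    if not items:
        raise ScreenEvalError("no cutoff with defined Youden J")
    best_cutoff, best_metrics = items[0]
    for c, m in items[1:]:
        if m.youden_j > best_metrics.youden_j + 1e-12 or (
            abs(m.youden_j - best_metrics.youden_j) <= 1e-12 and c < best_cutoff
        ):
            best_cutoff, best_metrics = c, m
    return best_cutoff, best_metrics


def agreement(table: ConfusionTable) -> Optional[float]:
    """Phi coefficient of a 2x2 agreement table.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) with (a, b, c, d) =
    (tp, fp, fn, tn).  Invariant under transposition, so the orientation of
    the two discordant cells does not matter.  Returns ``None`` when any
    margin is zero (phi undefined).
    """
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return None
    return (a * d - b * c) / math.sqrt(math.prod(margins))


def cutoff_table(
    scores: Sequence[float],
    labels: Sequence[bool],
    cutoffs: Sequence[float],
    rounded: bool = True,
) -> pd.DataFrame:
    """Accuracy-per-cutoff report table.

    With ``rounded=True`` percentages are half-up integers and J has one
    decimal (the display convention of the published table); otherwise full
    precision proportions are returned.
    """
    rows = []
    for c in cutoffs:
        m = diagnostic_metrics(confusion_at_cutoff(scores, labels, c))
        if rounded:
            fmt = lambda v: (
                None if v is None else int(round_half_up(100 * v))
            )
            rows.append(
                {
                    "cutoff": c,
                    "sensitivity_pct": fmt(m.sensitivity),
                    "specificity_pct": fmt(m.specificity),
                    "ppv_pct": fmt(m.ppv),
                    "npv_pct": fmt(m.npv),
                    "youden_j": None
                    if m.youden_j is None
                    else round_half_up(m.youden_j, 1),
                }
            )
        else:
            rows.append(
                {
                    "cutoff": c,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "npv": m.npv,
                    "youden_j": m.youden_j,
                }
            )
    return pd.DataFrame(rows)
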