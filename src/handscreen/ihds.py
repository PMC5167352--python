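"""Scoring, validation and stratification of the International HIV Dementia
Scale (IHDS).

The IHDS is a brief bedside screen for HIV-associated neurocognitive
disorders.  It has three subtests — motor speed (finger tapping),
psychomotor speed (Luria hand sequence) and a four-word delayed recall —
each scored 0 to 4 in half-point steps.  The total is the sum of the three
subtest scores and ranges 0 to 12; lower totals indicate worse performance.

Two conventions used throughout the package originate here:

* every IHDS value lives on the half-point grid {0, 0.5, ..., 12};
* screening strata split the total at 10 and 11: ``poor`` (total <= 10),
  ``average`` (10 < total <= 11) and ``high`` (total > 11).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

__all__ = [
    "IHDSValidationError",
    "IHDSResult",
    "ScreeningAction",
    "score_ihds",
    "stratify",
    "recommend_action",
    "on_grid",
    "DEFAULT_BOUNDARIES",
    "STRATUM_LABELS",
]

#: default stratum cut points (lower, upper) on the total score
DEFAULT_BOUNDARIES: tuple[float, float] = (10.0, 11.0)

#: HIV-positive stratum labels in increasing performance order
STRATUM_LABELS: tuple[str, str, str] = ("poor", "average", "high")


class IHDSValidationError(ValueError):
    """An IHDS value is out of range or off the half-point grid."""


def on_grid(value: float, step: float = 0.5) -> bool:
    """True if *value* lies on the scoring grid (multiples of *step*)."""
    return abs(value / step - round(value / step)) < 1e-9


def _check_subtest(name: str, value: float) -> float:
    if not on_grid(value):
        raise IHDSValidationError(
            f"{name} score {value!r} is not on the half-point grid"
        )
    if not 0.0 <= value <= 4.0:
        raise IHDSValidationError(f"{name} score {value!r} outside [0, 4]")
    return float(value)


@dataclass(frozen=True)
class IHDSResult:
    """Validated IHDS subtest scores and their total.

    The total is always ``motor_speed + psychomotor_speed + memory_recall``;
    construction fails if the stored total disagrees or any value is off
    grid / out of range.
    """

    motor_speed: float
    psychomotor_speed: float
    memory_recall: float
    total: float

    def __post_init__(self) -> None:
        _check_subtest("motor_speed", self.motor_speed)
        _check_subtest("psychomotor_speed", self.psychomotor_speed)
        _check_subtest("memory_recall", self.memory_recall)
        expected = self.motor_speed + self.psychomotor_speed + self.memory_recall
        if abs(self.total - expected) > 1e-9:
            raise IHDSValidationError(
                f"total {self.total!r} != sum of subtests {expected!r}"
            )


def score_ihds(
    motor_raw: float, psychomotor_raw: float, memory_raw: float
) -> IHDSResult:
    """Sum the three subtest scores into a validated :class:`IHDSResult`.

    Each input must lie on the half-point grid within [0, 4]; a violation
    raises :class:`IHDSValidationError` naming the offending subtest.
    """
    m = _check_subtest("motor_speed", motor_raw)
    p = _check_subtest("psychomotor_speed", psychomotor_raw)
    r = _check_subtest("memory_recall", memory_raw)
    return IHDSResult(m, p, r, m + p + r)


def stratify(
    total: float, boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
) -> str:
    """Map a total score to its screening stratum.

    ``total <= lower`` -> ``"poor"``; ``lower < total <= upper`` ->
    ``"average"``; ``total > upper`` -> ``"high"``.  Defaults reproduce the
    study strata: <=10, 10.5–11, 11.5–12.
    """
    lower, upper = boundaries
    if lower >= upper:
        raise IHDSValidationError(f"boundaries {boundaries!r} not ordered")
    if not on_grid(total) or not 0.0 <= total <= 12.0:
        raise IHDSValidationError(f"total {total!r} invalid for stratification")
    if total <= lower:
        return "poor"
    if total <= upper:
        return "average"
    return "high"


class ScreeningAction(IntEnum):
    """Recommended follow-up after an IHDS screen, ordered by urgency."""

    RESCREEN_6_MONTHS = 0
    EVALUATE = 1
    EVALUATE_URGENTLY = 2

    @property
    def label(self) -> str:
        return self.name.lower()


def recommend_action(total: float, has_complaints: bool) -> ScreeningAction:
    """Screening recommendation for a German-speaking clinic population.

    * total <= 10: neuropsychological evaluation without delay (higher
      likelihood of HIV-associated dementia);
    * 10 < total <= 11: neuropsychological evaluation;
    * total > 11 with active cognitive complaints: evaluation as well;
    * total > 11 without complaints: rescreen in six months.
    """
    if not on_grid(total) or not 0.0 <= total <= 12.0:
        raise IHDSValidationError(f"total {total!r} invalid")
    if total <= 10.0:
        return ScreeningAction.EVALUATE_URGENTLY
    if total <= 11.0:
        return ScreeningAction.EVALUATE
    if has_complaints:
        return ScreeningAction.EVALUATE
    return ScreeningAction.RESCREEN_6_MONTHS
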