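"""Demographically adjusted T-score norms for the screening total.

Regression-based norming in the Heaton/Rourke tradition, in three steps:

1. **Raw -> scaled.** Rank-normalise the reference distribution of raw
   totals: each distinct raw value maps through its empirical mid-rank
   quantile to a standard-normal deviate, rescaled to mean 10 / SD 3,
   rounded to the nearest integer and clipped.  Ties share a scaled score,
   so the mapping is monotone by construction.
2. **Scaled ~ demographics.** Ordinary least squares of the scaled score on
   age, education (years) and their interaction, predictors centred at
   reference means.  The residual SD uses denominator n - 4 (four
   regression parameters).
3. **T-score.**  T = 50 + 10 * (scaled - predicted) / residual SD, so T is
   the participant's standing relative to demographically comparable
   peers; T <= 40 (one residual SD below expectation) flags impairment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import round_half_up

__all__ = [
    "ScaledScoreTable",
    "NormativeModel",
    "NormativeError",
    "build_scaled_table",
    "fit_normative_model",
    "predict_scaled",
    "t_score",
    "is_impaired",
    "export_norm_tables",
    "T_IMPAIRMENT_CUTOFF",
]

T_IMPAIRMENT_CUTOFF = 40.0


class NormativeError(ValueError):
    pass


@dataclass(frozen=True)
class ScaledScoreTable:
    """Monotone raw -> scaled conversion built from a reference sample."""

    mapping: Mapping[float, int]
    target_mean: float = 10.0
    target_sd: float = 3.0
    clip_range: tuple[int, int] = (1, 19)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        raws = sorted(self.mapping)
        scaled = [self.mapping[r] for r in raws]
        if any(b < a for a, b in zip(scaled, scaled[1:])):
            raise NormativeError("scaled mapping is not monotone")
        lo, hi = self.clip_range
        if any(not lo <= s <= hi for s in scaled):
            raise NormativeError("scaled values outside clip range")

    def lookup(self, raw: float) -> int:
        """Scaled score for *raw*; unseen values use the nearest reference
        value (ties toward the lower, i.e. more conservative, raw score)."""
        if raw in self.mapping:
            return self.mapping[raw]
        raws = sorted(self.mapping)
        best = min(raws, key=lambda r: (abs(r - raw), r))
        return self.mapping[best]


def build_scaled_table(
    raw_scores: Sequence[float],
    clip_range: tuple[int, int] = (1, 19),
    target_mean: float = 10.0,
    target_sd: float = 3.0,
) -> ScaledScoreTable:
    """Rank-based normalisation of a reference sample of raw totals.

    Needs at least 30 reference observations.  The default clip range
    (1, 19) is the standard scaled-score span for mean 10 / SD 3; a
    narrower range (e.g. (1, 12)) can be configured.
    """
    arr = np.asarray(raw_scores, dtype=float)
    if arr.size < 30:
        raise NormativeError(
            f"reference sample too small ({arr.size} < 30 observations)"
        )
    values, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts)
    midq = (cum - counts / 2) / arr.size           # mid-rank quantile per value
    deviates = stats.norm.ppf(midq)
    scaled = np.floor(target_mean + target_sd * deviates + 0.5)  # half-up
    scaled = np.clip(scaled, *clip_range)
    scaled = np.maximum.accumulate(scaled)          # guard monotonicity
    mapping = {float(v): int(s) for v, s in zip(values, scaled)}
    return ScaledScoreTable(
        mapping=mapping,
        target_mean=target_mean,
        target_sd=target_sd,
        clip_range=clip_range,
    )


@dataclass(frozen=True)
class NormativeModel:
    """OLS norming model: scaled ~ age + education + age x education.

    Coefficients are on centred predictors; ``age_mean``/``education_mean``
    record the centring so predictions are reproducible from the persisted
    model alone.
    """

    intercept: float
    coef_age: float
    coef_education: float
    coef_interaction: float
    residual_sd: float
    reference_sample_size: int
    age_mean: float = 0.0
    education_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise NormativeError(f"residual_sd {self.residual_sd} must be > 0")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_age": self.coef_age,
            "coef_education": self.coef_education,
            "coef_interaction": self.coef_interaction,
            "residual_sd": self.residual_sd,
            "reference_sample_size": self.reference_sample_size,
            "age_mean": self.age_mean,
            "education_mean": self.education_mean,
        }


def fit_normative_model(
    scaled: Sequence[float],
    age: Sequence[float],
    education: Sequence[float],
) -> NormativeModel:
    """OLS fit of scaled scores on centred age, education and interaction."""
    y = np.asarray(scaled, dtype=float)
    a = np.asarray(age, dtype=float)
    e = np.asarray(education, dtype=float)
    if not (y.size == a.size == e.size):
        raise NormativeError("scaled, age and education must align")
    if y.size < 30:
        raise NormativeError(f"reference sample too small ({y.size} < 30)")
    a_mean, e_mean = float(a.mean()), float(e.mean())
    ac, ec = a - a_mean, e - e_mean
    X = sm.add_constant(np.column_stack([ac, ec, ac * ec]))
    if np.linalg.matrix_rank(X) < 4:
        raise NormativeError("degenerate design: predictors are collinear")
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(fit.ssr / (y.size - 4)))
    if resid_sd <= 0:
        # perfectly deterministic reference data; keep T finite
        resid_sd = np.finfo(float).tiny
    return NormativeModel(
        intercept=float(fit.params[0]),
        coef_age=float(fit.params[1]),
        coef_education=float(fit.params[2]),
        coef_interaction=float(fit.params[3]),
        residual_sd=resid_sd,
        reference_sample_size=int(y.size),
        age_mean=a_mean,
        education_mean=e_mean,
    )


def predict_scaled(model: NormativeModel, age: float, education: float) -> float:
    ac = np.asarray(age, dtype=float) - model.age_mean
    ec = np.asarray(education, dtype=float) - model.education_mean
    pred = (
        model.intercept
        + model.coef_age * ac
        + model.coef_education * ec
        + model.coef_interaction * ac * ec
    )
    return pred if np.ndim(pred) else float(pred)


def t_score(
    model: NormativeModel, scaled: float, age: float, education: float
) -> float:
    """T = 50 + 10 * (scaled - predicted) / residual SD."""
    pred = predict_scaled(model, age, education)
    t = 50.0 + 10.0 * (np.asarray(scaled, dtype=float) - pred) / model.residual_sd
    return t if np.ndim(t) else float(t)


def is_impaired(t: float, cutoff: float = T_IMPAIRMENT_CUTOFF) -> bool:
    """Impairment flag: T at or below the cutoff (default 40)."""
    return t <= cutoff


def export_norm_tables(
    table: ScaledScoreTable,
    model: NormativeModel,
    age_bands: Sequence[tuple[float, float]],
    education_bands: Sequence[tuple[float, float]],
    t_cutoff: float = T_IMPAIRMENT_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinic lookup tables: raw -> scaled, and per-demographic-cell the
    highest scaled score that still flags impairment (T <= cutoff).

    Band midpoints stand in for the cell's demographics.  A cell whose
    entire scaled range stays above the cutoff gets a null threshold.
    """
    if not age_bands or not education_bands:
        raise NormativeError("age and education bands must be non-empty")
    raw_rows = [
        {"raw": r, "scaled": table.mapping[r]} for r in sorted(table.mapping)
    ]
    raw_df = pd.DataFrame(raw_rows)

    lo, hi = table.clip_range
    cells = []
    for a_lo, a_hi in age_bands:
        for e_lo, e_hi in education_bands:
            a_mid, e_mid = (a_lo + a_hi) / 2, (e_lo + e_hi) / 2
            threshold = None
            for s in range(int(hi), int(lo) - 1, -1):
                if t_score(model, s, a_mid, e_mid) <= t_cutoff:
                    threshold = s
                    break
            cells.append(
                {
                    "age_band": f"{a_lo:g}-{a_hi:g}",
                    "education_band": f"{e_lo:g}-{e_hi:g}",
                    "age_mid": a_mid,
                    "education_mid": e_mid,
                    "impairment_scaled_threshold": threshold,
                }
            )
    return raw_df, pd.DataFrame(cells)
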