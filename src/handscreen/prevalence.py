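"""Two-phase (verification-sampling) prevalence estimation.

The study design screens everyone with the IHDS, splits the screened
population into performance strata, and fully evaluates a fixed-size random
subsample of each stratum.  Within stratum *i* with n_i screened, m_i
evaluated and e_i diagnosed cases, the population prevalence is estimated
by the stratified weighted sum

    adjusted prevalence = (1/N) * sum_i e_i * n_i / m_i,      N = sum_i n_i,

i.e. each verified case stands for n_i/m_i screened participants.  The
estimator is computed per diagnosis subtype and summed for overall HAND.
A percentile-bootstrap confidence interval (resampling evaluated records
within stratum) is provided as an extension; the point estimator itself
carries no design-based variance theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from ._util import round_half_up

__all__ = [
    "StratumSpec",
    "PrevalenceEstimate",
    "SubtypeShare",
    "PrevalenceError",
    "adjusted_prevalence",
    "subtype_breakdown",
    "bootstrap_ci",
    "strata_from_records",
]

HAND_SUBTYPES: tuple[str, ...] = ("ANI", "MND", "HAD")


class PrevalenceError(ValueError):
    pass


@dataclass(frozen=True)
class StratumSpec:
    """One screening stratum: counts feeding the weighted estimator."""

    name: str
    n_screened: int
    m_evaluated: int
    cases: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", dict(self.cases))
        if self.n_screened < 0 or self.m_evaluated < 0:
            raise PrevalenceError(f"stratum {self.name!r}: negative counts")
        if self.m_evaluated > self.n_screened:
            raise PrevalenceError(
                f"stratum {self.name!r}: evaluated {self.m_evaluated} exceeds "
                f"screened {self.n_screened}"
            )
        if any(c < 0 for c in self.cases.values()):
            raise PrevalenceError(f"stratum {self.name!r}: negative case count")
        total_cases = sum(self.cases.values())
        if total_cases > self.m_evaluated:
            raise PrevalenceError(
                f"stratum {self.name!r}: {total_cases} cases exceed "
                f"{self.m_evaluated} evaluated"
            )
        if total_cases > 0 and self.m_evaluated == 0:
            raise PrevalenceError(
                f"stratum {self.name!r}: cases with no evaluated records"
            )


@dataclass(frozen=True)
class PrevalenceEstimate:
    overall: float
    by_subtype: dict[str, float]
    N: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.overall <= 1 + 1e-12):
            raise PrevalenceError(f"overall {self.overall} outside [0, 1]")
        if abs(sum(self.by_subtype.values()) - self.overall) > 1e-12:
            raise PrevalenceError("subtype estimates do not sum to overall")


def adjusted_prevalence(strata: Sequence[StratumSpec]) -> PrevalenceEstimate:
    """Stratified weighted prevalence, per subtype and overall.

    Every subtype appearing in any stratum's case counts is reported;
    arithmetic is double precision (relative error well below 1e-12 at
    study scale).
    """
    if not strata:
        raise PrevalenceError("no strata")
    N = sum(s.n_screened for s in strata)
    if N <= 0:
        raise PrevalenceError("total screened population is empty")
    subtypes: list[str] = []
    for s in strata:
        for k in s.cases:
            if k not in subtypes:
                subtypes.append(k)
    by_subtype: dict[str, float] = {}
    for sub in subtypes:
        acc = 0.0
        for s in strata:
            e = s.cases.get(sub, 0)
            if e == 0:
                continue
            acc += e * s.n_screened / s.m_evaluated
        by_subtype[sub] = acc / N
    overall = sum(by_subtype.values())
    return PrevalenceEstimate(overall=overall, by_subtype=by_subtype, N=N)


class SubtypeShare(NamedTuple):
    absolute: float        # estimated population proportion of the subtype
    share_of_hand: float   # fraction of all HAND cases
    absolute_pct: int      # printed as integer percent (half-up)
    share_pct: int


def subtype_breakdown(
    estimate: PrevalenceEstimate,
) -> dict[str, SubtypeShare]:
    """Absolute and share-of-HAND percentages for each subtype.

    Shares are subtype/overall; both are reported at full precision and as
    half-up-rounded integer percentages, the display convention of the
    report tables.  An overall prevalence of zero leaves shares undefined.
    """
    if estimate.overall <= 0:
        raise PrevalenceError("shares undefined: overall prevalence is zero")
    out: dict[str, SubtypeShare] = {}
    for sub, p in estimate.by_subtype.items():
        share = p / estimate.overall
        out[sub] = SubtypeShare(
            absolute=p,
            share_of_hand=share,
            absolute_pct=int(round_half_up(100 * p)),
            share_pct=int(round_half_up(100 * share)),
        )
    return out


def bootstrap_ci(
    strata: Sequence[StratumSpec],
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    subtype: str | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the adjusted prevalence.

    Within each stratum the m_evaluated diagnoses are resampled with
    replacement from their empirical distribution (cases plus non-cases)
    and the weighted estimator is recomputed.  ``subtype=None`` gives the
    CI for overall HAND.  This is an extension beyond the point estimator:
    the original analysis reports no uncertainty interval.
    """
    rng = np.random.default_rng(seed)
    N = sum(s.n_screened for s in strata)
    draws = np.zeros(n_boot)
    for s in strata:
        if s.m_evaluated == 0:
            continue
        labels = list(s.cases.keys())
        counts = np.array([s.cases[k] for k in labels], dtype=float)
        if subtype is None:
            p_case = counts.sum() / s.m_evaluated
            e_star = rng.binomial(s.m_evaluated, p_case, size=n_boot)
        else:
            p_case = s.cases.get(subtype, 0) / s.m_evaluated
            e_star = rng.binomial(s.m_evaluated, p_case, size=n_boot)
        draws += e_star * s.n_screened / s.m_evaluated
    draws /= N
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def strata_from_records(
    records: Iterable,
    subtypes: Sequence[str] = HAND_SUBTYPES,
    control_stratum: str = "control",
) -> list[StratumSpec]:
    """Build :class:`StratumSpec` objects from classified cohort records.

    Controls are excluded: the weighted formula runs over the HIV-positive
    screening strata only.  Records must carry ``stratum``, ``evaluated``
    and (for evaluated ones) ``diagnosis``.
    """
    screened: dict[str, int] = {}
    evaluated: dict[str, int] = {}
    cases: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for rec in records:
        st = rec.stratum
        if st == control_stratum:
            continue
        if st not in screened:
            order.append(st)
            screened[st] = 0
            evaluated[st] = 0
            cases[st] = {sub: 0 for sub in subtypes}
        screened[st] += 1
        if getattr(rec, "evaluated", False):
            evaluated[st] += 1
            label = rec.diagnosis.label
            if label in cases[st]:
                cases[st][label] += 1
    return [
        StratumSpec(
            name=st,
            n_screened=screened[st],
            m_evaluated=evaluated[st],
            cases=cases[st],
        )
        for st in order
    ]
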