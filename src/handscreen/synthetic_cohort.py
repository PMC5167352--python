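"""Synthetic cohorts with the statistical structure of a two-phase
screening study in an HIV outpatient clinic.

Each HIV-positive participant carries a latent diagnosis class (NCN / ANI /
MND / HAD) drawn from a configurable mixture.  The class drives three
observable layers:

* an IHDS total: 12 minus a class-specific mean decrement plus Gaussian
  jitter, snapped to the half-point grid and decomposed into subtests;
* a neuropsychological profile: for impaired classes, a fixed number of
  cognitive domains is drawn uniformly and every battery test touching an
  affected domain has its Z-score shifted by the class displacement, with
  small Gaussian jitter on every test;
* a 22-item symptom questionnaire: the nine key items are Bernoulli with a
  class-specific endorsement rate.

Screening strata follow from the generated totals; a fixed-size random
subsample per stratum (plus all HIV-negative controls) receives the
profile and questionnaire, mirroring the verification design.  Everything
is deterministic given the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .frascati import (
    DNAAResponses,
    FRASCATI_DOMAINS,
    HANDDiagnosis,
    NeuropsychProfile,
    TestScore,
)
from .ihds import IHDSResult, stratify

__all__ = [
    "CLASSES",
    "BATTERY",
    "ConfigError",
    "SamplingError",
    "CohortConfig",
    "ParticipantRecord",
    "generate_cohort",
    "sample_evaluated",
]

CLASSES: tuple[str, ...] = ("NCN", "ANI", "MND", "HAD")

#: study battery: test name -> cognitive domain tags (1 or 2 per test).
#: ``lps_ut3`` carries only the auxiliary logical-thinking domain and can
#: therefore never contribute to a diagnosis.
BATTERY: tuple[tuple[str, frozenset[str]], ...] = (
    ("ravlt", frozenset({"learning_recall_memory"})),
    ("rvdlt", frozenset({"learning_recall_memory"})),
    ("rocf", frozenset({"sensory_perceptual", "learning_recall_memory"})),
    ("digit_span", frozenset({"attention_working_memory", "short_term_memory"})),
    ("lps_ut3", frozenset({"logical_thinking"})),
    ("d2", frozenset({"attention_working_memory"})),
    ("colour_word_interference", frozenset({"executive_function"})),
    ("cowa", frozenset({"language_verbal_fluency"})),
    ("tmt_a", frozenset({"psychomotor_speed"})),
    ("tmt_b", frozenset({"attention_working_memory", "executive_function"})),
    ("digit_symbol", frozenset({"psychomotor_speed"})),
    ("grooved_pegboard", frozenset({"motor_skills"})),
)

#: IHDS subtest deficit profile (motor : psychomotor : memory) used to
#: spread a total decrement over subtests; proportions follow the observed
#: poor-group-vs-control subtest gaps.
_SUBTEST_WEIGHTS = np.array([0.70, 1.17, 0.68])

# stratum-conditional clinical covariate medians (months since diagnosis,
# CD4 nadir, ART coverage) — carried for schema realism only
_CLINICAL = {
    "poor": {"months": 142.0, "nadir": 209.0, "art": 0.93},
    "average": {"months": 89.0, "nadir": 282.0, "art": 0.97},
    "high": {"months": 53.0, "nadir": 324.0, "art": 0.77},
}


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the field."""


class SamplingError(ValueError):
    pass


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name}: probability {value!r} outside [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and data-generating parameters.

    Defaults reproduce the Berlin study conditions: 480 screened, strata
    cut at totals 10 and 11, 30 evaluated per stratum plus 30 HIV-negative
    controls, latent mixture 57/20/17/6% over NCN/ANI/MND/HAD, and 10% of
    controls meeting ANI-like criteria.
    """

    n_screened: int = 480
    stratum_boundaries: tuple[float, float] = (10.0, 11.0)
    evaluated_per_stratum: int = 30
    n_controls: int = 30
    class_prevalence: tuple[float, float, float, float] = (0.57, 0.20, 0.17, 0.06)
    control_ani_rate: float = 0.10
    domain_shift: dict[str, float] = field(
        default_factory=lambda: {"NCN": 0.0, "ANI": -1.3, "MND": -1.3, "HAD": -2.2}
    )
    n_affected_domains: int = 2
    symptom_rate: dict[str, float] = field(
        default_factory=lambda: {"NCN": 0.05, "ANI": 0.05, "MND": 0.6, "HAD": 0.8}
    )
    nonkey_symptom_rate: float = 0.2
    ihds_effect: dict[str, float] = field(
        default_factory=lambda: {"NCN": 0.0, "ANI": 0.5, "MND": 1.4, "HAD": 3.0}
    )
    noise_sd: float = 0.1
    ihds_noise_sd: float = 0.5
    key_items: frozenset[int] = field(
        default_factory=lambda: frozenset(range(1, 10))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_screened <= 0:
            raise ConfigError(f"n_screened: must be positive, got {self.n_screened}")
        if self.evaluated_per_stratum < 0:
            raise ConfigError("evaluated_per_stratum: must be non-negative")
        if self.n_controls < 0:
            raise ConfigError("n_controls: must be non-negative")
        lo, hi = self.stratum_boundaries
        if lo >= hi:
            raise ConfigError(f"stratum_boundaries: {lo!r} >= {hi!r}")
        if len(self.class_prevalence) != len(CLASSES):
            raise ConfigError("class_prevalence: must have four entries")
        for p in self.class_prevalence:
            _check_prob("class_prevalence", p)
        if abs(sum(self.class_prevalence) - 1.0) > 1e-9:
            raise ConfigError(
                f"class_prevalence: sums to {sum(self.class_prevalence)!r}, not 1"
            )
        _check_prob("control_ani_rate", self.control_ani_rate)
        _check_prob("nonkey_symptom_rate", self.nonkey_symptom_rate)
        if self.n_affected_domains < 2:
            raise ConfigError(
                "n_affected_domains: must be >= 2 (two-domain diagnostic rule)"
            )
        if self.n_affected_domains > len(FRASCATI_DOMAINS):
            raise ConfigError(
                f"n_affected_domains: exceeds {len(FRASCATI_DOMAINS)} domains"
            )
        for name, mapping in (
            ("domain_shift", self.domain_shift),
            ("symptom_rate", self.symptom_rate),
            ("ihds_effect", self.ihds_effect),
        ):
            missing = set(CLASSES) - set(mapping)
            if missing:
                raise ConfigError(f"{name}: missing class(es) {sorted(missing)}")
        for cls, p in self.symptom_rate.items():
            _check_prob(f"symptom_rate[{cls}]", p)
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd: must be > 0, got {self.noise_sd}")
        if self.ihds_noise_sd <= 0:
            raise ConfigError(f"ihds_noise_sd: must be > 0, got {self.ihds_noise_sd}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["key_items"] = sorted(self.key_items)
        return d


@dataclass
class ParticipantRecord:
    """One row of the cohort table.

    Clinical covariates (CD4 counts, months since diagnosis, ART status)
    are absent for HIV-negative controls; the neuropsychological profile
    and questionnaire exist only once the record has been evaluated.
    ``true_class`` is the generator's latent label and would not exist in
    real data.
    """

    id: str
    hiv_positive: bool
    age: int
    education: int
    ihds: IHDSResult
    stratum: str
    months_since_diagnosis: Optional[float] = None
    cd4_current: Optional[float] = None
    cd4_nadir: Optional[float] = None
    on_art: Optional[bool] = None
    true_class: Optional[str] = None
    evaluated: bool = False
    profile: Optional[NeuropsychProfile] = None
    dnaa: Optional[DNAAResponses] = None
    diagnosis: Optional[HANDDiagnosis] = None


def _snap(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(x) * 2.0) / 2.0, 0.0, 12.0)


def _decompose_total(total: float) -> IHDSResult:
    """Split a grid total into subtests, spreading the decrement from the
    ceiling proportionally to the empirical subtest deficit profile
    (largest-remainder apportionment in half-point units, capped at 4
    points per subtest)."""
    units = int(round((12.0 - total) * 2))           # half-point units lost
    share = _SUBTEST_WEIGHTS / _SUBTEST_WEIGHTS.sum()
    raw = units * share
    alloc = np.floor(raw).astype(int)
    rema = raw - alloc
    # distribute leftover units by largest remainder, deterministic tie-break
    for _ in range(units - alloc.sum()):
        order = sorted(range(3), key=lambda i: (-rema[i], i))
        for i in order:
            if alloc[i] < 8:
                alloc[i] += 1
                rema[i] = -1.0
                break
    # cap overflow at 8 units (4 points) per subtest
    for i in range(3):
        while alloc[i] > 8:
            spill = alloc[i] - 8
            alloc[i] = 8
            for j in sorted(range(3), key=lambda k: (alloc[k], k)):
                if j != i and alloc[j] < 8:
                    alloc[j] += spill
                    break
    m, p, r = (4.0 - alloc * 0.5).tolist()
    return IHDSResult(m, p, r, m + p + r)


def _draw_demographics(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    # discretised normals matched to the cohort's median/IQR
    age = np.clip(np.round(rng.normal(43.0, 11.9, n)), 19, 80).astype(int)
    edu = np.clip(np.round(rng.normal(15.0, 3.0, n)), 8, 25).astype(int)
    return age, edu


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate the screened HIV-positive population plus controls.

    All records carry demographics and IHDS scores; profiles and
    questionnaires are attached later by :func:`sample_evaluated`.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_screened

    classes = rng.choice(len(CLASSES), size=n, p=list(config.class_prevalence))
    age, edu = _draw_demographics(rng, n)
    effects = np.array([config.ihds_effect[CLASSES[c]] for c in classes])
    totals = _snap(12.0 - effects + rng.normal(0.0, config.ihds_noise_sd, n))

    records: list[ParticipantRecord] = []
    for i in range(n):
        stratum = stratify(float(totals[i]), config.stratum_boundaries)
        clin = _CLINICAL[stratum]
        months = float(rng.lognormal(math.log(clin["months"]), 0.9))
        cd4_now = float(rng.lognormal(math.log(554.0), 0.45))
        cd4_nadir = float(rng.lognormal(math.log(clin["nadir"]), 0.7))
        on_art = bool(rng.random() < clin["art"])
        records.append(
            ParticipantRecord(
                id=f"P{i + 1:04d}",
                hiv_positive=True,
                age=int(age[i]),
                education=int(edu[i]),
                ihds=_decompose_total(float(totals[i])),
                stratum=stratum,
                months_since_diagnosis=round(months, 1),
                cd4_current=round(cd4_now, 0),
                cd4_nadir=round(cd4_nadir, 0),
                on_art=on_art,
                true_class=CLASSES[classes[i]],
            )
        )

    nc = config.n_controls
    if nc:
        ctrl_classes = np.where(rng.random(nc) < config.control_ani_rate, "ANI", "NCN")
        c_age, c_edu = _draw_demographics(rng, nc)
        c_effects = np.array([config.ihds_effect[c] for c in ctrl_classes])
        c_totals = _snap(12.0 - c_effects + rng.normal(0.0, config.ihds_noise_sd, nc))
        for i in range(nc):
            records.append(
                ParticipantRecord(
                    id=f"C{i + 1:04d}",
                    hiv_positive=False,
                    age=int(c_age[i]),
                    education=int(c_edu[i]),
                    ihds=_decompose_total(float(c_totals[i])),
                    stratum="control",
                    true_class=str(ctrl_classes[i]),
                )
            )
    return records


def _generate_profile(
    rng: np.random.Generator, config: CohortConfig, cls: str
) -> tuple[NeuropsychProfile, DNAAResponses]:
    shift = config.domain_shift[cls]
    affected: frozenset[str] = frozenset()
    if cls != "NCN" and shift != 0.0:
        affected = frozenset(
            rng.choice(
                sorted(FRASCATI_DOMAINS),
                size=config.n_affected_domains,
                replace=False,
            )
        )
    tests = []
    for name, domains in BATTERY:
        mean = shift if domains & affected else 0.0
        tests.append(
            TestScore(name=name, z=float(mean + rng.normal(0.0, config.noise_sd)), domains=domains)
        )
    p_key = config.symptom_rate[cls]
    answers = tuple(
        bool(rng.random() < (p_key if (i + 1) in config.key_items else config.nonkey_symptom_rate))
        for i in range(22)
    )
    return NeuropsychProfile(tuple(tests)), DNAAResponses(answers, config.key_items)


def sample_evaluated(
    records: Sequence[ParticipantRecord],
    config: CohortConfig,
    strict: bool = True,
) -> list[ParticipantRecord]:
    """Select the verification subsample and attach profiles in place.

    ``evaluated_per_stratum`` HIV-positive records per stratum are chosen
    uniformly without replacement; all controls are evaluated.  With
    ``strict=True`` a stratum smaller than the request raises
    :class:`SamplingError`; with ``strict=False`` the whole stratum is
    taken instead (useful in simulation studies where a tail seed can
    leave a stratum slightly short).  Returns the evaluated records.
    Deterministic given ``config.seed`` (an independent stream from
    cohort generation).
    """
    rng = np.random.default_rng([config.seed, 1])
    by_stratum: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        if rec.hiv_positive:
            by_stratum.setdefault(rec.stratum, []).append(idx)

    chosen: set[int] = set()
    for stratum in sorted(by_stratum):
        idxs = by_stratum[stratum]
        m = config.evaluated_per_stratum
        if len(idxs) < m:
            if strict:
                raise SamplingError(
                    f"stratum {stratum!r} has {len(idxs)} members, "
                    f"cannot sample {m}"
                )
            m = len(idxs)
        picked = rng.choice(len(idxs), size=m, replace=False)
        chosen.update(idxs[j] for j in sorted(picked))

    evaluated: list[ParticipantRecord] = []
    for idx, rec in enumerate(records):
        if idx in chosen or not rec.hiv_positive:
            rec.evaluated = True
            rec.profile, rec.dnaa = _generate_profile(rng, config, rec.true_class)
            evaluated.append(rec)
    return evaluated
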