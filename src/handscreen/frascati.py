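"""Rule-based HAND classification from neuropsychological Z-scores and a
symptom questionnaire (operational Frascati criteria).

A participant *fails* a test when its demographically corrected Z-score is
at or below the failure threshold (default -1 SD), and *severely fails* it
at or below the severe threshold (default -2 SD).  The diagnostic rules:

* **HAND** — at least two failed tests that can be assigned to at least two
  *distinct* cognitive domains (each test is tagged with one or two domains;
  the assignment must pick different domains for different tests).
* **HAD** (HIV-associated dementia) — the same two-test/two-domain rule
  restricted to severely failed tests.
* Non-HAD HAND splits on self-reported everyday-functioning interference:
  **MND** (mild neurocognitive disorder) if any of the nine key
  questionnaire items is endorsed, otherwise **ANI** (asymptomatic
  neurocognitive impairment).
* Otherwise **NCN** (neurocognitively normal).

Domains follow the eight-domain vocabulary of the study battery; the
auxiliary "logical thinking" domain is carried on profiles but never counts
toward the two-domain requirement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "FRASCATI_DOMAINS",
    "AUXILIARY_DOMAINS",
    "KNOWN_DOMAINS",
    "ProfileError",
    "TestScore",
    "NeuropsychProfile",
    "DNAAResponses",
    "HANDDiagnosis",
    "HAND_LABELS",
    "SEVERITY_ORDER",
    "classify",
    "classify_cohort",
]

#: cognitive domains that count toward the two-domain impairment rule
FRASCATI_DOMAINS: frozenset[str] = frozenset(
    {
        "learning_recall_memory",
        "sensory_perceptual",
        "attention_working_memory",
        "executive_function",
        "language_verbal_fluency",
        "psychomotor_speed",
        "motor_skills",
        "short_term_memory",
    }
)

#: domains carried for test interpretation but excluded from the rule
AUXILIARY_DOMAINS: frozenset[str] = frozenset({"logical_thinking"})

KNOWN_DOMAINS: frozenset[str] = FRASCATI_DOMAINS | AUXILIARY_DOMAINS

HAND_LABELS: tuple[str, ...] = ("NCN", "ANI", "MND", "HAD")

#: label severity for monotonicity checks (ANI and MND share a rank)
SEVERITY_ORDER: dict[str, int] = {"NCN": 0, "ANI": 1, "MND": 1, "HAD": 2}


class ProfileError(ValueError):
    """Invalid neuropsychological profile or questionnaire input."""


@dataclass(frozen=True)
class TestScore:
    """One battery test: name, Z-score and its 1–2 domain tags."""

    name: str
    z: float
    domains: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", frozenset(self.domains))
        if not self.domains:
            raise ProfileError(f"test {self.name!r} carries no domain")
        if len(self.domains) > 2:
            raise ProfileError(f"test {self.name!r} carries >2 domains")
        unknown = self.domains - KNOWN_DOMAINS
        if unknown:
            raise ProfileError(
                f"test {self.name!r} has unknown domain(s) {sorted(unknown)}"
            )


@dataclass(frozen=True)
class NeuropsychProfile:
    """Per-test Z-scores for one participant; test names must be unique."""

    tests: tuple[TestScore, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tests", tuple(self.tests))
        names = [t.name for t in self.tests]
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise ProfileError(f"duplicate test name(s) {dupes}")


@dataclass(frozen=True)
class DNAAResponses:
    """22 yes/no questionnaire answers; nine key items flag symptoms.

    Items are 1-indexed.  The key subset defaults to items 1–9 and is
    configuration: the original German questionnaire does not number its
    key items in the published text.
    """

    answers: tuple[bool, ...]
    key_items: frozenset[int] = field(
        default_factory=lambda: frozenset(range(1, 10))
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "answers", tuple(bool(a) for a in self.answers))
        object.__setattr__(self, "key_items", frozenset(self.key_items))
        if len(self.answers) != 22:
            raise ProfileError(
                f"expected 22 questionnaire answers, got {len(self.answers)}"
            )
        if len(self.key_items) != 9:
            raise ProfileError(f"expected 9 key items, got {len(self.key_items)}")
        if not self.key_items <= set(range(1, 23)):
            raise ProfileError("key items must be item indices in 1..22")

    @property
    def symptomatic(self) -> bool:
        """Any key item endorsed (any-yes rule)."""
        return any(self.answers[i - 1] for i in self.key_items)


@dataclass(frozen=True)
class HANDDiagnosis:
    label: str
    failed_tests: tuple[str, ...]
    severely_failed_tests: tuple[str, ...]
    symptomatic: bool


def _spans_two_domains(tests: Sequence[TestScore]) -> bool:
    """Can two of these tests be assigned two *distinct* Frascati domains?

    Each test may be matched to any one of its own (Frascati) domain tags;
    tests tagged only with auxiliary domains never participate.  With a
    requirement of exactly two representatives, an exhaustive pairwise scan
    is an exact matching test.
    """
    eligible = [t for t in tests if t.domains & FRASCATI_DOMAINS]
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            da = a.domains & FRASCATI_DOMAINS
            db = b.domains & FRASCATI_DOMAINS
            # distinct representatives exist unless both are the same singleton
            if da != db or len(da) > 1:
                return True
    return False


def classify(
    profile: NeuropsychProfile,
    dnaa: DNAAResponses,
    fail_threshold: float = -1.0,
    severe_threshold: float = -2.0,
) -> HANDDiagnosis:
    """Apply the operational Frascati rules to one participant.

    Thresholds are inclusive (Z <= threshold fails) and configurable;
    ``severe_threshold <= fail_threshold < 0`` is required, which guarantees
    that a HAD diagnosis always also satisfies the HAND rule.
    """
    if not profile.tests:
        raise ProfileError("profile is empty")
    if not (severe_threshold <= fail_threshold < 0):
        raise ProfileError(
            f"need severe <= fail < 0, got {severe_threshold}, {fail_threshold}"
        )

    failed = [t for t in profile.tests if t.z <= fail_threshold]
    severe = [t for t in profile.tests if t.z <= severe_threshold]
    symptomatic = dnaa.symptomatic

    if _spans_two_domains(severe):
        label = "HAD"
    elif _spans_two_domains(failed):
        label = "MND" if symptomatic else "ANI"
    else:
        label = "NCN"
    return HANDDiagnosis(
        label=label,
        failed_tests=tuple(t.name for t in failed),
        severely_failed_tests=tuple(t.name for t in severe),
        symptomatic=symptomatic,
    )


class DataError(ValueError):
    """A record violates the cohort data contract."""


def classify_cohort(
    records: Iterable,
    fail_threshold: float = -1.0,
    severe_threshold: float = -2.0,
) -> dict[str, Counter]:
    """Classify every evaluated record in place; return per-stratum counts.

    Records are any objects with ``evaluated``, ``profile``, ``dnaa``,
    ``stratum`` and a writable ``diagnosis`` attribute (the cohort record
    type of :mod:`handscreen.synthetic_cohort` qualifies).  Non-evaluated
    records are left unannotated.
    """
    counts: dict[str, Counter] = {}
    for rec in records:
        if not getattr(rec, "evaluated", False):
            continue
        if rec.profile is None or rec.dnaa is None:
            raise DataError(
                f"evaluated record {getattr(rec, 'id', '?')!r} lacks "
                "profile or questionnaire data"
            )
        diag = classify(rec.profile, rec.dnaa, fail_threshold, severe_threshold)
        rec.diagnosis = diag
        counts.setdefault(rec.stratum, Counter())[diag.label] += 1
    return counts
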