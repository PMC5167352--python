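from collections import Counter

import numpy as np
import pytest

from oracles import oracle_hand_label

from handscreen.frascati import (
    DNAAResponses,
    FRASCATI_DOMAINS,
    NeuropsychProfile,
    ProfileError,
    SEVERITY_ORDER,
    TestScore,
    classify,
    classify_cohort,
)
from handscreen.synthetic_cohort import CohortConfig, generate_cohort, sample_evaluated

KEY = frozenset(range(1, 10))


def dnaa(yes_items=()):
    return DNAAResponses(tuple(i + 1 in set(yes_items) for i in range(22)), KEY)


def profile(*tests):
    return NeuropsychProfile(tuple(TestScore(*t) for t in tests))


def test_two_severe_failures_in_two_domains_is_had():
    p = profile(
        ("tmt_b", -2.1, {"attention_working_memory", "executive_function"}),
        ("grooved_pegboard", -2.3, {"motor_skills"}),
        ("ravlt", 0.0, {"learning_recall_memory"}),
    )
    assert classify(p, dnaa()).label == "HAD"


def test_unimpaired_profile_is_ncn_regardless_of_symptoms():
    p = profile(("ravlt", 0.0, {"learning_recall_memory"}), ("d2", 0.2, {"attention_working_memory"}))
    assert classify(p, dnaa(range(1, 10))).label == "NCN"


def test_key_items_split_ani_from_mnd():
    p = profile(
        ("ravlt", -1.2, {"learning_recall_memory"}),
        ("cowa", -1.1, {"language_verbal_fluency"}),
    )
    assert classify(p, dnaa()).label == "ANI"
    assert classify(p, dnaa([3])).label == "MND"
    # a yes outside the key subset does not make the case symptomatic
    assert classify(p, dnaa([15])).label == "ANI"


def test_single_shared_domain_does_not_qualify():
    """Two failures tagged with the same single domain fail the
    two-distinct-domain requirement."""
    p = profile(
        ("tmt_a", -1.5, {"psychomotor_speed"}),
        ("digit_symbol", -1.5, {"psychomotor_speed"}),
    )
    assert classify(p, dnaa()).label == "NCN"


def test_multidomain_test_supplies_a_distinct_representative():
    # tmt_b can stand for executive function while CWI holds it too only
    # if one of them can move to a different domain
    p = profile(
        ("tmt_b", -1.5, {"attention_working_memory", "executive_function"}),
        ("colour_word_interference", -1.5, {"executive_function"}),
    )
    assert classify(p, dnaa()).label == "ANI"


def test_auxiliary_domain_never_counts():
    p = profile(
        ("lps_ut3", -3.0, {"logical_thinking"}),
        ("ravlt", -3.0, {"learning_recall_memory"}),
    )
    assert classify(p, dnaa()).label == "NCN"


def test_had_requires_two_severe_domains():
    p = profile(
        ("ravlt", -2.5, {"learning_recall_memory"}),
        ("cowa", -1.4, {"language_verbal_fluency"}),
    )
    # only one severe failure: HAND yes, HAD no
    assert classify(p, dnaa([1])).label == "MND"


def test_input_validation():
    with pytest.raises(ProfileError):
        classify(NeuropsychProfile(()), dnaa())
    with pytest.raises(ProfileError, match="unknown domain"):
        TestScore("x", -1.0, frozenset({"astrology"}))
    with pytest.raises(ProfileError):
        DNAAResponses((True,) * 21, KEY)
    with pytest.raises(ProfileError):
        profile(("a", 0.0, {"motor_skills"}), ("a", 0.0, {"motor_skills"}))


def _random_profile(rng):
    domains = sorted(FRASCATI_DOMAINS) + ["logical_thinking"]
    n_tests = rng.integers(1, 7)
    tests = []
    for i in range(n_tests):
        k = rng.integers(1, 3)
        doms = frozenset(rng.choice(domains, size=k, replace=False))
        z = float(rng.normal(-1.0, 1.2))
        tests.append(TestScore(f"t{i}", z, doms))
    return NeuropsychProfile(tuple(tests))


def test_classifier_matches_exhaustive_oracle(rng):
    """Label agrees with the brute-force subset/assignment evaluator on
    random small profiles."""
    for _ in range(300):
        p = _random_profile(rng)
        symptomatic = bool(rng.random() < 0.5)
        d = dnaa([1] if symptomatic else [])
        got = classify(p, d).label
        want = oracle_hand_label(p.tests, symptomatic)
        assert got == want


def test_severity_monotone_under_single_score_drop(rng):
    """Lowering one Z-score never makes the label less severe."""
    for _ in range(200):
        p = _random_profile(rng)
        d = dnaa([2] if rng.random() < 0.5 else [])
        before = SEVERITY_ORDER[classify(p, d).label]
        i = int(rng.integers(0, len(p.tests)))
        drop = float(rng.uniform(0.1, 3.0))
        tests = list(p.tests)
        tests[i] = TestScore(tests[i].name, tests[i].z - drop, tests[i].domains)
        after = SEVERITY_ORDER[classify(NeuropsychProfile(tuple(tests)), d).label]
        assert after >= before


def test_had_always_satisfies_hand_rule(rng):
    for _ in range(200):
        p = _random_profile(rng)
        diag = classify(p, dnaa())
        if diag.label == "HAD":
            assert len(diag.failed_tests) >= 2
            assert set(diag.severely_failed_tests) <= set(diag.failed_tests)


def test_classify_cohort_conserves_counts(classified_cohort):
    evaluated = [r for r in classified_cohort if r.evaluated]
    assert len(evaluated) == 120
    assert all(r.diagnosis is not None for r in evaluated)
    assert all(r.diagnosis is None for r in classified_cohort if not r.evaluated)
    counts = Counter(r.diagnosis.label for r in evaluated)
    assert sum(counts.values()) == 120


def test_degenerate_mixture_classifies_all_ncn():
    cfg = CohortConfig(
        n_screened=60,
        class_prevalence=(1.0, 0.0, 0.0, 0.0),
        control_ani_rate=0.0,
        evaluated_per_stratum=5,
        noise_sd=0.01,
        seed=7,
    )
    records = generate_cohort(cfg)
    sample_evaluated(records, cfg, strict=False)
    classify_cohort(records)
    assert all(r.diagnosis.label == "NCN" for r in records if r.evaluated)


def test_evaluated_record_without_profile_is_a_data_error(classified_cohort):
    from handscreen.frascati import DataError

    rec = next(r for r in classified_cohort if r.evaluated)
    broken = type(rec)(**{**rec.__dict__, "profile": None})
    with pytest.raises(DataError, match=broken.id):
        classify_cohort([broken])


def test_recovered_class_counts_track_latent_classes():
    """With low noise, per-class diagnosis counts stay within the binomial
    95% band of the latent class counts among evaluated records."""
    cfg = CohortConfig(seed=11)
    records = generate_cohort(cfg)
    sample_evaluated(records, cfg)
    classify_cohort(records)
    evaluated = [r for r in records if r.evaluated]
    # HAND status itself is recovered essentially perfectly at default noise
    mismatch = sum(
        1
        for r in evaluated
        if (r.true_class != "NCN") != (r.diagnosis.label != "NCN")
    )
    assert mismatch <= 3  # 95% band for n=120, p<=0.005
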