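import io

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from handscreen.normative import (
    NormativeError,
    NormativeModel,
    ScaledScoreTable,
    build_scaled_table,
    export_norm_tables,
    fit_normative_model,
    is_impaired,
    predict_scaled,
    t_score,
)
from handscreen.synthetic_cohort import CohortConfig, generate_cohort


def oracle_scaled_mapping(raw, clip=(1, 19)):
    """Independent rank-quantile construction: per-element average ranks
    converted to quantiles, then to mean-10/SD-3 deviates."""
    arr = np.asarray(raw, float)
    q = (rankdata(arr) - 0.5) / arr.size
    scaled = np.clip(np.floor(10 + 3 * norm.ppf(q) + 0.5), *clip)
    return {float(v): int(s) for v, s in zip(arr, scaled)}


def test_scaled_table_matches_rank_quantile_oracle():
    cfg = CohortConfig(seed=3)
    totals = [r.ihds.total for r in generate_cohort(cfg) if r.hiv_positive]
    table = build_scaled_table(totals)
    oracle = oracle_scaled_mapping(totals)
    assert table.mapping == {v: oracle[v] for v in table.mapping}


def test_scaled_table_midpoint_and_endpoints():
    raw = list(range(1, 102))  # 101 distinct values, median 51
    table = build_scaled_table(raw)
    assert table.mapping[51.0] == 10
    assert table.mapping[101.0] == max(table.mapping.values())
    scaled = [table.mapping[float(v)] for v in raw]
    assert all(a <= b for a, b in zip(scaled, scaled[1:]))


def test_scaled_table_respects_clip_range():
    raw = list(range(1, 102))
    table = build_scaled_table(raw, clip_range=(1, 12))
    assert max(table.mapping.values()) <= 12
    assert min(table.mapping.values()) >= 1


def test_scaled_table_needs_thirty_observations():
    with pytest.raises(NormativeError, match="too small"):
        build_scaled_table(list(range(10)))


def test_lookup_uses_nearest_reference_value():
    table = ScaledScoreTable({8.0: 5, 10.0: 9, 12.0: 13})
    assert table.lookup(10.0) == 9
    assert table.lookup(11.4) == 13
    assert table.lookup(9.0) == 5  # tie resolves to the lower raw value


def test_noiseless_fit_recovers_exact_coefficients(rng):
    age = rng.uniform(20, 70, 200)
    edu = rng.uniform(8, 20, 200)
    a0, b_a, b_e, b_i = 10.0, -0.05, 0.2, 0.004
    ac, ec = age - age.mean(), edu - edu.mean()
    scaled = a0 + b_a * ac + b_e * ec + b_i * ac * ec
    model = fit_normative_model(scaled, age, edu)
    assert model.coef_age == pytest.approx(b_a, abs=1e-8)
    assert model.coef_education == pytest.approx(b_e, abs=1e-8)
    assert model.coef_interaction == pytest.approx(b_i, abs=1e-8)
    assert model.residual_sd < 1e-6


def test_fit_with_independent_predictors(rng):
    """Scaled scores unrelated to demographics: coefficients near zero and
    residual SD near the sample SD (n = 5000)."""
    n = 5000
    age = rng.uniform(20, 70, n)
    edu = rng.uniform(8, 20, n)
    scaled = rng.normal(10, 3, n)
    model = fit_normative_model(scaled, age, edu)
    assert model.coef_age == pytest.approx(0.0, abs=0.02)
    assert model.coef_education == pytest.approx(0.0, abs=0.05)
    assert model.residual_sd == pytest.approx(scaled.std(ddof=1), rel=0.01)


def test_noisy_fit_recovers_coefficients_within_three_se(rng):
    n = 480
    age = rng.normal(43, 12, n)
    edu = rng.normal(15, 3, n)
    ac, ec = age - age.mean(), edu - edu.mean()
    truth = dict(intercept=10.0, age=-0.06, edu=0.25, inter=0.01)
    scaled = (
        truth["intercept"] + truth["age"] * ac + truth["edu"] * ec
        + truth["inter"] * ac * ec + rng.normal(0, 2.5, n)
    )
    model = fit_normative_model(scaled, age, edu)
    X = sm.add_constant(np.column_stack([ac, ec, ac * ec]))
    se = sm.OLS(scaled, X).fit().bse
    assert abs(model.intercept - truth["intercept"]) < 3 * se[0]
    assert abs(model.coef_age - truth["age"]) < 3 * se[1]
    assert abs(model.coef_education - truth["edu"]) < 3 * se[2]
    assert abs(model.coef_interaction - truth["inter"]) < 3 * se[3]


def test_fit_rejects_degenerate_design():
    with pytest.raises(NormativeError, match="collinear"):
        fit_normative_model([10.0] * 40, [50.0] * 40, [12.0] * 40)


def test_t_score_identities():
    model = NormativeModel(
        intercept=10.0, coef_age=-0.05, coef_education=0.2, coef_interaction=0.0,
        residual_sd=2.5, reference_sample_size=480, age_mean=43.0, education_mean=15.0,
    )
    pred = predict_scaled(model, 50, 12)
    assert t_score(model, pred, 50, 12) == pytest.approx(50.0)
    assert t_score(model, pred - model.residual_sd, 50, 12) == pytest.approx(40.0)
    assert t_score(model, pred + model.residual_sd, 50, 12) == pytest.approx(60.0)
    assert is_impaired(40.0) and not is_impaired(40.0001)


def test_t_score_affine_invariance(rng):
    model = NormativeModel(10.0, -0.05, 0.2, 0.003, 2.5, 480, 43.0, 15.0)
    a, b = 3.7, -12.0  # common affine rescaling of both scores
    rescaled = NormativeModel(
        a * 10.0 + b, a * -0.05, a * 0.2, a * 0.003, a * 2.5, 480, 43.0, 15.0
    )
    for _ in range(20):
        s, age, edu = rng.uniform(1, 19), rng.uniform(20, 70), rng.uniform(8, 20)
        assert t_score(rescaled, a * s + b, age, edu) == pytest.approx(
            t_score(model, s, age, edu), abs=1e-9
        )


def test_balanced_reference_gives_mean_50_sd_10(rng):
    n = 5000
    age = rng.normal(43, 12, n)
    edu = rng.normal(15, 3, n)
    scaled = 10 - 0.04 * (age - 43) + 0.2 * (edu - 15) + rng.normal(0, 2.8, n)
    model = fit_normative_model(scaled, age, edu)
    t = t_score(model, scaled, age, edu)
    assert np.mean(t) == pytest.approx(50.0, abs=0.2)
    assert np.std(t, ddof=1) == pytest.approx(10.0, abs=0.2)


def _bands():
    return [(20, 39), (40, 59)], [(8, 12), (13, 18)]


def test_norm_table_thresholds_roundtrip_through_t_score():
    model = NormativeModel(10.0, -0.05, 0.2, 0.003, 2.5, 480, 43.0, 15.0)
    table = ScaledScoreTable({float(v): v for v in range(1, 20)})
    age_bands, edu_bands = _bands()
    _, cells = export_norm_tables(table, model, age_bands, edu_bands)
    for _, cell in cells.iterrows():
        thr = cell["impairment_scaled_threshold"]
        assert thr is not None
        a, e = cell["age_mid"], cell["education_mid"]
        assert t_score(model, thr, a, e) <= 40.0
        assert t_score(model, thr + 1, a, e) > 40.0


def test_norm_table_thresholds_shrink_with_wider_residual_sd():
    table = ScaledScoreTable({float(v): v for v in range(1, 20)})
    age_bands, edu_bands = _bands()
    prev = None
    for sd in (1.0, 2.0, 3.0, 4.0):
        model = NormativeModel(10.0, -0.05, 0.2, 0.003, sd, 480, 43.0, 15.0)
        _, cells = export_norm_tables(table, model, age_bands, edu_bands)
        thr = cells["impairment_scaled_threshold"].to_numpy(dtype=float)
        if prev is not None:
            assert (thr <= prev).all()
        prev = thr


def test_norm_tables_serialise_losslessly():
    model = NormativeModel(10.0, -0.05, 0.2, 0.003, 2.5, 480, 43.0, 15.0)
    table = ScaledScoreTable({float(v): min(v + 2, 19) for v in range(1, 13)})
    raw_df, cells = export_norm_tables(table, model, *_bands())
    buf = io.StringIO()
    raw_df.to_csv(buf, index=False)
    buf.seek(0)
    assert pd.read_csv(buf).equals(raw_df)


def test_t_screen_lands_between_raw_cutoffs(pipeline_result):
    """Screening at T <= 40 operates between the raw-10 and raw-11 cutoffs
    on a synthetic cohort."""
    from handscreen.screen_eval import confusion_at_cutoff, diagnostic_metrics

    res = pipeline_result
    evaluated = [r for r in res.records if r.evaluated]
    scores = np.array([r.ihds.total for r in evaluated])
    hand = np.array([r.diagnosis.label != "NCN" for r in evaluated])
    m10 = diagnostic_metrics(confusion_at_cutoff(scores, hand, 10))
    m11 = diagnostic_metrics(confusion_at_cutoff(scores, hand, 11))
    assert m10.sensitivity <= res.t_metrics.sensitivity <= m11.sensitivity
    assert m11.specificity <= res.t_metrics.specificity <= m10.specificity
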