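import numpy as np
import pandas as pd
import pytest

from cwlearn.features import (
    DesignMatrix,
    adjacent_correlation,
    bin_trials,
    confidence_regressions,
    residual_confidence,
    summarize_coefficients,
    update_regression_r,
    zscore,
)


def _trace_frame(p, conf, **extra):
    n = len(p)
    base = dict(
        prediction=p,
        confidence=conf,
        flag_first=np.zeros(n, dtype=bool),
        session=np.zeros(n, dtype=int),
    )
    base.update(extra)
    return pd.DataFrame(base)


# ---------------------------------------------------------------------------
# design matrix and z-scoring


def test_design_matrix_zscores_columns(rng):
    x = rng.normal(3.0, 2.0, size=200)
    dm = DesignMatrix({"x": x, "raw": x.copy()}, no_zscore=("raw",))
    M = dm.matrix()
    assert dm.names == ["intercept", "x", "raw"]
    assert abs(M[:, 1].mean()) < 1e-10
    assert M[:, 1].std() == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(M[:, 2], x)


def test_design_matrix_rejects_missing_and_ragged():
    with pytest.raises(ValueError):
        DesignMatrix({"x": np.array([1.0, np.nan])})
    with pytest.raises(ValueError):
        DesignMatrix({"x": np.ones(3), "y": np.ones(4)})


def test_zscore_rejects_constant():
    with pytest.raises(ValueError):
        zscore(np.ones(10))


# ---------------------------------------------------------------------------
# residual confidence


def test_residual_confidence_is_zero_when_in_design_span(rng):
    p = rng.uniform(0.1, 0.9, size=500)
    conf = 2.0 + 3.0 * p**2
    resid = residual_confidence(_trace_frame(p, conf))
    assert np.abs(resid).max() < 1e-10


def test_residual_confidence_is_orthogonal_to_predictors(rng):
    p = rng.uniform(0.05, 0.95, size=1000)
    conf = rng.normal(size=1000) - np.log(p * (1 - p))
    resid = residual_confidence(_trace_frame(p, conf))
    for col in [np.ones_like(p), p, p**2, np.log(p), np.log(1 - p)]:
        assert abs(resid @ col) < 1e-8
    assert resid.var() < conf.var()


def test_residual_confidence_rejects_constant_prediction():
    with pytest.raises(ValueError):
        residual_confidence(_trace_frame(np.full(50, 0.5), np.random.default_rng(0).normal(size=50)))


def test_residual_confidence_decorrelates_from_u_shape(default_cohort):
    g = default_cohort.traces.query("subject == 0 and not flag_first")
    resid = residual_confidence(g.assign(flag_first=False))
    p2 = zscore(g.prediction) ** 2
    raw_r = np.corrcoef(g.confidence, p2)[0, 1]
    resid_r = np.corrcoef(resid, p2)[0, 1]
    assert raw_r > 0.1
    assert abs(resid_r) < 0.02


# ---------------------------------------------------------------------------
# adjacent correlation and binning


def test_adjacent_correlation_closed_cases(rng):
    assert adjacent_correlation(np.arange(100.0)) == pytest.approx(1.0)
    iid = rng.normal(size=100_000)
    assert abs(adjacent_correlation(iid)) < 0.01
    # AR(1) with coefficient 0.5 has lag-1 autocorrelation 0.5
    n = 100_000
    e = rng.normal(size=n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = 0.5 * x[t - 1] + e[t]
    assert adjacent_correlation(x) == pytest.approx(0.5, abs=0.01)


def test_adjacent_correlation_respects_session_boundaries(rng):
    # two sessions with opposite trends: cross-boundary pair would flip sign
    x = np.concatenate([np.arange(50.0), np.arange(50.0)])
    sessions = np.repeat([0, 1], 50)
    assert adjacent_correlation(x, sessions) == pytest.approx(1.0)


def test_adjacent_correlation_rejects_constant():
    with pytest.raises(ValueError):
        adjacent_correlation(np.ones(100))


def test_bin_trials_means_and_partial_bin_drop():
    x = np.arange(1.0, 11.0)
    assert np.allclose(bin_trials(x, 1), x)
    assert np.allclose(bin_trials(np.full(10, 3.14), 10), [3.14])
    assert np.allclose(bin_trials(x, 5), [3.0, 8.0])
    assert np.allclose(bin_trials(x, 4), [2.5, 6.5])  # trailing pair dropped
    with pytest.raises(ValueError):
        bin_trials(x, 0)
    with pytest.raises(ValueError):
        bin_trials(x, 11)


def test_bin_trials_does_not_mix_sessions():
    x = np.concatenate([np.zeros(7), np.ones(7)])
    sessions = np.repeat([0, 1], 7)
    assert np.allclose(bin_trials(x, 5, sessions), [0.0, 1.0])


# ---------------------------------------------------------------------------
# update regression


def _update_frame(rng, n=2000, interaction=0.0):
    s = rng.normal(size=n)
    c = rng.normal(size=n)
    kl = 0.7 * s - 0.4 * c + interaction * s * c
    return pd.DataFrame(
        dict(
            surprise_bits=s + 5,
            confidence=2 * c + 3,
            kl_update=kl,
            flag_first=np.zeros(n, dtype=bool),
        )
    )


def test_update_regression_perfect_fit_for_linear_construction(rng):
    df = _update_frame(rng)
    assert update_regression_r(df) == pytest.approx(1.0, abs=1e-10)


def test_update_regression_interaction_never_hurts(rng):
    df = _update_frame(rng, interaction=0.3)
    r0 = update_regression_r(df, include_interaction=False)
    r1 = update_regression_r(df, include_interaction=True)
    assert r1 >= r0
    assert r1 == pytest.approx(1.0, abs=1e-10)


def test_update_regression_invariant_to_affine_rescaling(rng):
    df = _update_frame(rng, interaction=0.1)
    scaled = df.assign(
        surprise_bits=3.0 * df.surprise_bits - 1.0, confidence=0.2 * df.confidence + 7.0
    )
    assert update_regression_r(scaled) == pytest.approx(update_regression_r(df), abs=1e-12)


def test_update_regression_requires_enough_trials(rng):
    with pytest.raises(ValueError):
        update_regression_r(_update_frame(rng, n=50))


# ---------------------------------------------------------------------------
# confidence battery


def test_confidence_battery_signs_on_default_simulation(behavioral_table):
    assert behavioral_table.loc["beta_p2", "mean"] > 0
    assert behavioral_table.loc["beta_prev_surprise", "mean"] < 0
    assert behavioral_table.loc["beta_log_tsc", "mean"] > 0
    assert abs(behavioral_table.loc["corr_conf_p", "mean"]) < 0.15


def test_confidence_identical_to_prediction_gives_unit_correlation(rng):
    p = rng.uniform(0.1, 0.9, size=400)
    df = _trace_frame(p, p.copy()).assign(
        subject=0,
        surprise_bits=rng.normal(size=400) + 2,
        kl_update=rng.random(400),
        trials_since_cp=np.arange(1, 401),
    )
    out = confidence_regressions(df, residual_outcome_for_history=False)
    assert out.loc[0, "corr_conf_p"] == pytest.approx(1.0)


def test_confidence_battery_rejects_underpowered_subject(rng):
    df = _trace_frame(rng.uniform(0.2, 0.8, 5), rng.normal(size=5)).assign(
        subject=0, surprise_bits=1.0, kl_update=0.1, trials_since_cp=np.arange(1, 6)
    )
    with pytest.raises(ValueError):
        confidence_regressions(df)


def test_summary_table_matches_direct_computation(rng):
    per_subject = pd.DataFrame({"subject": range(10), "b": rng.normal(0.5, 0.1, size=10)})
    out = summarize_coefficients(per_subject)
    v = per_subject["b"]
    assert out.loc["b", "mean"] == pytest.approx(v.mean())
    assert out.loc["b", "sem"] == pytest.approx(v.std(ddof=1) / np.sqrt(10))
    assert out.loc["b", "n"] == 10
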