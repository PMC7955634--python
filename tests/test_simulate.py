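"""Synthetic cohort generator: event-time sampler, marginals, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ticjoint as tj
from ticjoint.params import ConfigurationError, MARKERS
from ticjoint.simulate import (
    BEYOND_CENSORING,
    BinnedMarginal,
    CalibrationError,
    default_survival_truth,
    BASELINE_LOG_LEVEL,
)


# ---------------------------------------------------------------------------
# Event-time sampler


def test_constant_hazard_closed_form_event_time():
    # H(T) = lambda*T = -ln u  ->  T = -ln(u)/lambda; u = e^-1, lambda = 0.5
    T = tj.simulate_event_time(lambda t: np.zeros_like(t), lambda t: np.full_like(t, 0.5),
                               u=np.exp(-1.0), censor_time=25.0)
    assert T == pytest.approx(2.0, abs=1e-8)


def test_event_time_u_one_gives_zero_and_invalid_u_raises():
    T = tj.simulate_event_time(lambda t: np.zeros_like(t), lambda t: np.ones_like(t), u=1.0)
    assert T == 0.0
    for bad in (0.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            tj.simulate_event_time(
                lambda t: np.zeros_like(t), lambda t: np.ones_like(t), u=bad
            )


def test_event_time_censoring_sentinel():
    # tiny hazard: cumulative hazard over the window < -ln(u)
    T = tj.simulate_event_time(
        lambda t: np.zeros_like(t), lambda t: np.full_like(t, 1e-6), u=0.1
    )
    assert T == BEYOND_CENSORING


def test_event_times_ks_vs_exponential():
    """5000 draws under constant hazard are Exponential(lambda); KS test
    not rejected at alpha = 0.01 (median p over 10 seeds)."""
    lam = 0.5
    pvals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=5000)
        u = np.clip(u, np.finfo(float).tiny, 1.0)
        T = tj.simulate_event_time(
            lambda t: np.zeros_like(t),
            lambda t: np.full_like(t, lam),
            u=u,
            censor_time=1000.0,
        )
        assert np.all(np.isfinite(T))
        pvals.append(stats.kstest(T, stats.expon(scale=1 / lam).cdf).pvalue)
    assert np.median(pvals) > 0.01


# ---------------------------------------------------------------------------
# Covariate and random-effect sampling


def test_covariate_marginals_match_published_fractions():
    cfg = tj.default_cohort_config(n_patients=10000, seed=42)
    cov = tj.sample_fixed_covariates(cfg)
    n = len(cov)
    for col, p in (
        ("sex_male", 728 / 891),
        ("tbi", 343 / 891),
        ("penetrating", 385 / 891),
    ):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(cov[col].mean() - p) < 3 * se, col
    assert cov["age"].between(15, 95).all()
    assert cov["iss"].between(0, 75).all()
    assert (cov["iss"] == cov["iss"].astype(int)).all()


def test_random_effects_zero_covariance_gives_zero_effects():
    cfg = tj.default_cohort_config(
        n_patients=50,
        seed=0,
        re_covariance={m: np.zeros((2, 2)) for m in MARKERS},
    )
    re = tj.sample_random_effects(cfg)
    for m in MARKERS:
        np.testing.assert_allclose(re.effects[m], 0.0)


def test_random_effects_sample_covariance_converges():
    cfg = tj.default_cohort_config(n_patients=40000, seed=9)
    re = tj.sample_random_effects(cfg)
    for m in MARKERS:
        target = np.asarray(cfg.re_covariance[m])
        sample = np.cov(re.effects[m].T)
        # tolerance sized to ~4 Monte-Carlo standard errors at n=40000
        np.testing.assert_allclose(sample, target, rtol=0.1, atol=2e-3)


def test_binned_marginal_validation():
    with pytest.raises(ConfigurationError):
        BinnedMarginal(edges=(0, 1), probs=(0.5, 0.5))
    with pytest.raises(ConfigurationError):
        BinnedMarginal(edges=(0, 1, 2), probs=(0.7, 0.2))


# ---------------------------------------------------------------------------
# Cohort generation


def test_generate_cohort_deterministic_per_seed():
    cfg = tj.default_cohort_config(n_patients=150, seed=13)
    cov1, lon1, sur1, _ = tj.generate_cohort(cfg)
    cov2, lon2, sur2, _ = tj.generate_cohort(cfg)
    pd.testing.assert_frame_equal(cov1, cov2)
    pd.testing.assert_frame_equal(lon1, lon2)
    pd.testing.assert_frame_equal(sur1, sur2)
    cov3, _, _, _ = tj.generate_cohort(tj.default_cohort_config(n_patients=150, seed=14))
    assert not cov3.equals(cov1)


def test_generate_cohort_empty():
    cov, lon, sur, truth = tj.generate_cohort(tj.default_cohort_config(n_patients=0))
    assert len(cov) == 0 and len(lon) == 0 and len(sur) == 0


def test_measurements_respect_death_and_window():
    cfg = tj.default_cohort_config(n_patients=400, seed=5)
    cov, lon, sur, truth = tj.generate_cohort(cfg)
    surv = sur.set_index("patient_id")
    for pid, grp in lon.groupby("patient_id"):
        T = surv.loc[pid, "time_h"]
        if surv.loc[pid, "death"] == 1:
            assert (grp["time_h"] < T).all()
        else:
            assert (grp["time_h"] <= cfg.censor_time).all()
    assert (lon["time_h"] >= 0).all()


def test_observations_per_patient_near_published_density():
    # 2062 observations / 891 patients ~= 2.31 per retained patient
    cfg = tj.default_cohort_config(n_patients=4000, seed=11)
    _, lon, _, _ = tj.generate_cohort(cfg)
    per_patient = len(lon) / lon["patient_id"].nunique()
    assert abs(per_patient - 2062 / 891) / (2062 / 891) < 0.10


def test_full_missingness_yields_no_records():
    cfg = tj.default_cohort_config(n_patients=30, seed=1, per_draw_missingness=1.0)
    _, lon, _, _ = tj.generate_cohort(cfg)
    assert len(lon) == 0


# ---------------------------------------------------------------------------
# Event-rate calibration


def test_calibrated_default_death_fraction():
    cfg = tj.default_cohort_config(n_patients=5000, seed=23)
    _, _, sur, _ = tj.generate_cohort(cfg)
    assert abs(sur["death"].mean() - 0.068) < 0.012


def test_calibration_is_fixed_point_at_default_truth():
    cfg = tj.default_cohort_config(n_patients=891, seed=0)
    m = tj.calibrate_event_rate(cfg, 0.068, n_mc=20000)
    assert abs(np.log(m)) < 0.15


def test_calibration_monotone_in_target():
    cfg = tj.default_cohort_config(n_patients=891, seed=0)
    m_low = tj.calibrate_event_rate(cfg, 0.03, n_mc=5000)
    m_high = tj.calibrate_event_rate(cfg, 0.15, n_mc=5000)
    assert m_low < m_high


def test_calibration_unattainable_rate_raises():
    cfg = tj.default_cohort_config(n_patients=891, seed=0)
    with pytest.raises(CalibrationError):
        tj.calibrate_event_rate(cfg, 0.999, n_mc=2000, log_mult_bounds=(-1.0, 1.0))


def test_calibrated_multiplier_hits_target_when_applied():
    cfg = tj.default_cohort_config(n_patients=891, seed=0)
    target = 0.12
    m = tj.calibrate_event_rate(cfg, target, n_mc=20000)
    shifted = tj.default_cohort_config(
        n_patients=8000,
        seed=77,
        true_survival=default_survival_truth(BASELINE_LOG_LEVEL + np.log(m)),
    )
    _, _, sur, _ = tj.generate_cohort(shifted)
    assert abs(sur["death"].mean() - target) < 0.015
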