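"""Inference engine: posterior densities, inner Newton, diagnostics, and
small-scale estimation checks against external references."""

import numpy as np
import pandas as pd
import pytest

import ticjoint as tj
from ticjoint.data import CohortData
from ticjoint.inference import (
    EngineConfig,
    JointParams,
    UnidentifiableModelError,
    _JointModel,
    fit,
    gelman_rubin,
    joint_log_posterior,
)
from ticjoint.io import preprocess
from ticjoint.longitudinal import longitudinal_loglik, linear_predictor
from ticjoint.params import MARKERS, PriorSpec, RandomEffects, SplineBasisSpec
from ticjoint.simulate import (
    default_longitudinal_truth,
    default_re_covariance,
    default_survival_truth,
)
from ticjoint.survival import cumulative_hazard, hazard

from conftest import make_cohort


def _default_params() -> JointParams:
    return JointParams(
        longitudinal=default_longitudinal_truth(),
        survival=default_survival_truth(),
        re_covariance=default_re_covariance(),
    )


def _tiny_cohort() -> CohortData:
    covariates = pd.DataFrame(
        {
            "patient_id": [0, 1, 2],
            "age": [30.0, 55.0, 70.0],
            "sex_male": [1, 1, 0],
            "iss": [10.0, 30.0, 20.0],
            "tbi": [0, 1, 0],
            "penetrating": [1, 0, 0],
        }
    )
    longitudinal = pd.DataFrame(
        {
            "patient_id": [0, 0, 1, 2, 2, 2],
            "time_h": [0.1, 4.0, 2.0, 0.5, 6.0, 12.0],
            "marker": [
                "FactorII",
                "logDDimer",
                "FactorII",
                "FactorII",
                "logDDimer",
                "FactorII",
            ],
            "value": [80.0, 1.2, 60.0, 90.0, 0.4, 75.0],
        }
    )
    survival = pd.DataFrame(
        {"patient_id": [0, 1, 2], "time_h": [25.0, 8.0, 25.0], "death": [0, 1, 0]}
    )
    return CohortData(covariates=covariates, longitudinal=longitudinal, survival=survival)


def _random_effects(seed: int, n: int = 3) -> RandomEffects:
    rng = np.random.default_rng(seed)
    return RandomEffects(
        patient_ids=np.arange(n),
        effects={
            "FactorII": rng.normal(0.0, [5.0, 0.1], size=(n, 2)),
            "logDDimer": rng.normal(0.0, [0.5, 0.02], size=(n, 2)),
        },
    )


def test_joint_log_posterior_difference_matches_component_oracle():
    """Changing only the random effects cancels the parameter prior, so the
    log-posterior difference must equal the difference of the longitudinal,
    survival and random-effect densities computed with independent public
    functions patient by patient."""
    data = _tiny_cohort()
    params = _default_params()
    re_a = _random_effects(1)
    re_b = _random_effects(2)

    def component_sum(re: RandomEffects) -> float:
        total = longitudinal_loglik(
            params.longitudinal, re, data.longitudinal, data.covariates
        )
        for _, row in data.covariates.iterrows():
            pid = row["patient_id"]
            srow = data.survival.set_index("patient_id").loc[pid]

            def eta_fn(t):
                return {
                    m: linear_predictor(params.longitudinal, re, row, t, m, patient_id=pid)
                    for m in MARKERS
                }

            H = cumulative_hazard(
                float(srow["time_h"]), params.survival, eta_fn, row, n_nodes=10
            )
            total -= H
            if srow["death"] == 1:
                t_ev = float(srow["time_h"])
                total += np.log(
                    hazard(t_ev, params.survival, eta_fn(np.array([t_ev])), row)[0]
                )
            # bivariate normal random-effect density
            for m in MARKERS:
                cov = np.asarray(params.re_covariance[m])
                u = re.lookup(pid, m)
                inv = np.linalg.inv(cov)
                _, logdet = np.linalg.slogdet(cov)
                total += float(
                    -0.5 * u @ inv @ u - 0.5 * (logdet + 2 * np.log(2 * np.pi))
                )
        return total

    got = joint_log_posterior(params, re_a, data, n_quad_nodes=10) - joint_log_posterior(
        params, re_b, data, n_quad_nodes=10
    )
    expected = component_sum(re_a) - component_sum(re_b)
    assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_joint_log_posterior_nonfinite_params_gives_minus_inf():
    data = _tiny_cohort()
    params = _default_params()
    params.survival.alpha = np.array([np.nan, 0.8])
    assert joint_log_posterior(params, _random_effects(1), data) == -np.inf


def test_fit_rejects_zero_event_cohort():
    data = _tiny_cohort()
    data.survival["death"] = 0
    with pytest.raises(UnidentifiableModelError):
        fit(data, engine=EngineConfig(mode="fast", chains=2, draws=10))


def test_inner_newton_gradient_matches_finite_differences():
    data = _tiny_cohort()
    model = _JointModel(data, PriorSpec(), SplineBasisSpec(), 10)
    g = model.layout.pack(_default_params())
    rng = np.random.default_rng(0)
    U = rng.normal(0.0, 0.3, size=(model.n, 4))
    U[:, (0,)] *= 10  # intercept-scale perturbations
    grad, negH = model._u_grad_neghess(g, U)
    eps = 1e-6
    for i in range(model.n):
        for k in range(4):
            Up = U.copy()
            Up[i, k] += eps
            Um = U.copy()
            Um[i, k] -= eps
            fd = (
                model.logpost(g, Up, include_jacobian=False)
                - model.logpost(g, Um, include_jacobian=False)
            ) / (2 * eps)
            assert grad[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_inner_newton_finds_stationary_point():
    data = _tiny_cohort()
    model = _JointModel(data, PriorSpec(), SplineBasisSpec(), 10)
    g = model.layout.pack(_default_params())
    U, negH, ok = model.solve_u(g)
    assert ok
    grad, _ = model._u_grad_neghess(g, U)
    assert np.max(np.abs(grad)) < 1e-6
    # negative Hessian positive definite at the mode
    assert np.all(np.linalg.eigvalsh(negH) > 0)


def test_gelman_rubin_identical_chains_is_exactly_one():
    rng = np.random.default_rng(4)
    one = rng.normal(size=400)
    chains = np.stack([one, one, one, one])
    assert gelman_rubin(chains, split=False) == 1.0


def test_gelman_rubin_iid_chains_near_one_and_shifted_chains_large():
    rng = np.random.default_rng(5)
    iid = rng.normal(size=(4, 4000))
    r = gelman_rubin(iid, split=True)
    assert 0.99 < r < 1.01
    shifted = iid + np.array([0.0, 0.0, 0.0, 10.0])[:, None]
    assert gelman_rubin(shifted) > 2.0


def test_prior_only_fit_recovers_prior_scale():
    """With no data, posterior draws of an unscaled coefficient must match
    its prior (mean 0, sd = configured scale)."""
    engine = EngineConfig(mode="mcmc", chains=4, draws=400, warmup_steps=1000, seed=3)
    res = fit(None, priors=PriorSpec(autoscale=False), engine=engine)
    draws = res.draw_array("gamma.age")
    # mean within ~3 MC standard errors (autocorrelation-inflated), sd near
    # the prior scale
    assert abs(np.mean(draws)) < 0.3
    assert np.std(draws) == pytest.approx(2.5, rel=0.25)


def test_fit_is_deterministic_given_seed():
    data = make_cohort(60, seed=19)
    engine = EngineConfig(mode="fast", seed=11, chains=2, draws=50)
    s1 = fit(data, engine=engine).summary()
    s2 = fit(data, engine=engine).summary()
    pd.testing.assert_frame_equal(s1, s2)


def test_gamma_estimates_agree_with_cox_model_when_alpha_zero():
    """With the biomarker associations generated at zero, the survival
    submodel reduces to a proportional-hazards regression on the fixed
    covariates; posterior medians should agree with a lifelines CoxPH fit
    on the same data to within joint-model shrinkage."""
    lifelines = pytest.importorskip("lifelines")
    cfg = tj.default_cohort_config(n_patients=400, seed=31)
    cfg.true_survival.alpha = np.zeros(2)
    cov, lon, sur, _ = tj.generate_cohort(cfg)
    data, _ = preprocess(
        CohortData(covariates=cov, longitudinal=lon, survival=sur), censor_time=25.0
    )
    res = fit(data, engine=EngineConfig(mode="fast", seed=2, chains=2, draws=200))
    s = res.summary().set_index("parameter")

    df = data.covariates.merge(data.survival, on="patient_id")
    cph = lifelines.CoxPHFitter()
    cph.fit(
        df[["age", "sex_male", "iss", "tbi", "penetrating", "time_h", "death"]],
        duration_col="time_h",
        event_col="death",
    )
    for c in ("tbi", "penetrating"):
        ours = float(s.loc[f"gamma.{c}", "median"])
        cox = float(cph.params_[c])
        assert abs(ours - cox) < 0.5, (c, ours, cox)



def test_recovery_error_shrinks_with_sample_size(recovery_fit, small_fit):
    """Posterior medians of the longitudinal fixed effects approach the
    generating truth as the cohort grows (n=1000 vs n~110)."""
    truth = default_longitudinal_truth()

    def mae(res):
        s = res.summary().set_index("parameter")
        errs = []
        for m in MARKERS:
            scale = truth[m].sigma
            errs.append(abs(s.loc[f"{m}.intercept", "median"] - truth[m].intercept) / scale)
            errs.append(
                abs(s.loc[f"{m}.slope", "median"] - truth[m].slope) / (scale / 10.0)
            )
        return float(np.mean(errs))

    assert mae(recovery_fit) < mae(small_fit)
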