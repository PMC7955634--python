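"""Posterior reporting: hazard-ratio tables, trajectory prediction with
shrinkage, slope distributions, and dynamic conditional survival."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ticjoint.params import COVARIATES, MARKERS
from ticjoint.reporting import (
    conditional_survival,
    coefficient_table,
    hazard_ratio_table,
    individual_slope_distribution,
    predict_trajectory,
)
from ticjoint.survival import SplineDomainError


# ---------------------------------------------------------------------------
# Hazard-ratio table


def test_hazard_ratio_table_zero_coefficients_give_unit_ratios(small_fit):
    """exp(0) = 1: a posterior concentrated at zero for every log-hazard
    coefficient must report HR = 1.00 with a degenerate [1, 1] interval."""
    zeroed = dict(small_fit.draws)
    for name in list(zeroed):
        if name.startswith("gamma.") or name.startswith("alpha."):
            zeroed[name] = np.zeros_like(zeroed[name])
    fit0 = dataclasses.replace(small_fit, draws=zeroed)
    tab = hazard_ratio_table(fit0).table
    np.testing.assert_allclose(tab[["hr", "lower", "upper"]].to_numpy(), 1.0)


def test_hazard_ratio_table_matches_sorted_draw_oracle(small_fit):
    """Median and central interval recomputed directly from the sorted draws."""
    tab = hazard_ratio_table(small_fit).table
    for cov in COVARIATES:
        draws = np.sort(np.exp(small_fit.draw_array(f"gamma.{cov}")))
        n = len(draws)
        med = draws[(n - 1) // 2]  # lower of the two middle order statistics
        assert tab.loc[cov, "hr"] == pytest.approx(med, rel=1e-12)
        assert tab.loc[cov, "lower"] == pytest.approx(
            np.percentile(draws, 2.5), rel=1e-12
        )
        assert tab.loc[cov, "upper"] == pytest.approx(
            np.percentile(draws, 97.5), rel=1e-12
        )


def test_hazard_ratio_median_commutes_with_exp(small_fit):
    """The reported HR equals exp(median of the log-scale draws) exactly."""
    tab = hazard_ratio_table(small_fit).table
    for j, m in enumerate(MARKERS):
        coef = small_fit.draw_array(f"alpha.{m}")
        n = len(coef)
        log_med = np.sort(coef)[(n - 1) // 2]
        assert tab.loc[m, "hr"] == pytest.approx(np.exp(log_med), rel=1e-12)


def test_coefficient_table_shape_and_interval_order(small_fit):
    tab = coefficient_table(small_fit)
    assert len(tab) == len(MARKERS) * (2 + len(COVARIATES))
    assert (tab["lower"] <= tab["median"]).all()
    assert (tab["median"] <= tab["upper"]).all()


# ---------------------------------------------------------------------------
# Trajectory prediction and shrinkage


def test_recordless_patient_mean_is_exact_population_line(small_fit):
    """A patient known only through covariates has random effects at their
    exact zero mean: the predicted mean curve must equal the population
    line computed by hand from the posterior draws."""
    x = {"age": 45.0, "sex_male": 1, "iss": 25.0, "tbi": 0, "penetrating": 1}
    grid = np.linspace(0.0, 24.0, 7)
    traj = predict_trajectory(small_fit, x, time_grid=grid, marker="FactorII")

    from ticjoint.inference import GlobalsLayout

    layout = GlobalsLayout(small_fit.spline_spec.n_basis)
    sl = layout.marker_slices["FactorII"]
    flat = small_fit.flat_g()
    xv = np.array([x[k] for k in COVARIATES], dtype=float)
    pop_int = flat[:, sl.start] + flat[:, sl.start + 2 : sl.start + 7] @ xv
    expected = pop_int.mean() + flat[:, sl.start + 1].mean() * grid
    np.testing.assert_allclose(traj.mean, expected, rtol=1e-12)
    # exactly linear in time: vanishing second differences
    np.testing.assert_allclose(np.diff(traj.mean, n=2), 0.0, atol=1e-9)


def test_shrinkage_narrows_interval_for_well_observed_patient(small_fit):
    """Without any records the interval carries the full between-patient
    dispersion; conditioning on a patient's own measurements shrinks it, so
    the most-observed patient's interval must be narrower."""
    counts = (
        small_fit.data.longitudinal.query("marker == 'FactorII'")
        .groupby("patient_id")
        .size()
    )
    pid = counts.idxmax()
    row = small_fit.covariates.set_index("patient_id").loc[pid]
    x = {k: row[k] for k in COVARIATES}
    grid = np.array([0.0, 12.0, 24.0])
    out_of_sample = predict_trajectory(small_fit, x, time_grid=grid)
    in_sample = predict_trajectory(small_fit, pid, time_grid=grid)
    width_out = out_of_sample.upper - out_of_sample.lower
    width_in = in_sample.upper - in_sample.lower
    assert np.all(width_out > width_in)


def test_trajectory_median_slope_matches_slope_distribution(small_fit):
    """predict_trajectory and individual_slope_distribution must agree on a
    patient's posterior-median slope (same draws, same statistic)."""
    dist = individual_slope_distribution(small_fit)
    for pid in small_fit.patient_ids[:3]:
        for m in MARKERS:
            traj = predict_trajectory(small_fit, pid, marker=m)
            row = dist[(dist["patient_id"] == pid) & (dist["marker"] == m)]
            assert traj.median_slope == pytest.approx(
                float(row["median_slope"].iloc[0]), rel=1e-12
            )


def test_slope_distribution_covers_cohort_with_zero_reference(small_fit):
    dist = individual_slope_distribution(small_fit)
    assert len(dist) == len(small_fit.patient_ids) * len(MARKERS)
    assert dist.attrs["reference_line"] == 0.0
    assert np.isfinite(dist["median_slope"]).all()


def test_predict_trajectory_validation_errors(small_fit):
    with pytest.raises(KeyError):
        predict_trajectory(small_fit, small_fit.patient_ids[0], marker="INR")
    with pytest.raises(KeyError):
        predict_trajectory(small_fit, "no-such-patient")
    with pytest.raises(KeyError):
        predict_trajectory(small_fit, {"age": 40.0})  # missing covariates


# ---------------------------------------------------------------------------
# Dynamic conditional survival


def test_conditional_survival_telescopes_exactly(small_fit):
    """S(0 -> t1 + t2) = S(0 -> t1) * S(t1 -> t1 + t2) draw by draw: the
    cumulative hazard over [0, t1+t2] splits additively at t1."""
    pid = small_fit.patient_ids[0]
    t1, t2 = 6.0, 10.0
    full = conditional_survival(small_fit, pid, 0.0, t1 + t2, return_draws=True)
    first = conditional_survival(small_fit, pid, 0.0, t1, return_draws=True)
    second = conditional_survival(small_fit, pid, t1, t2, return_draws=True)
    np.testing.assert_allclose(full, first * second, rtol=1e-10)


def test_conditional_survival_is_probability_and_decreases_with_horizon(small_fit):
    pid = small_fit.patient_ids[1]
    probs = [conditional_survival(small_fit, pid, 2.0, h) for h in (2.0, 8.0, 20.0)]
    for p in probs:
        assert 0.0 < p <= 1.0
    assert probs[0] >= probs[1] >= probs[2]


def test_conditional_survival_validation(small_fit):
    pid = small_fit.patient_ids[0]
    with pytest.raises(ValueError):
        conditional_survival(small_fit, pid, -1.0, 5.0)
    with pytest.raises(ValueError):
        conditional_survival(small_fit, pid, 1.0, 0.0)
    with pytest.raises(SplineDomainError):
        conditional_survival(small_fit, pid, 20.0, 10.0)  # beyond the boundary
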