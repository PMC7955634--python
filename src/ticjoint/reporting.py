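"""Posterior reporting: hazard-ratio tables, individual trajectories with
shrinkage, per-patient slope distributions, and dynamic conditional-survival
prediction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .inference import GlobalsLayout, JointModelFit
from .params import COVARIATES, MARKERS
from .survival import SplineDomainError, bspline_basis, gauss_legendre_nodes


# ---------------------------------------------------------------------------
# Hazard ratios


@dataclass
class HazardRatioTable:
    table: pd.DataFrame  # index: covariate/marker; columns: hr, lower, upper

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["lower"] <= t["hr"]).all() and (t["hr"] <= t["upper"]).all()):
            raise AssertionError("hazard-ratio interval must bracket the median")
        if not (t[["hr", "lower", "upper"]] > 0).all().all():
            raise AssertionError("hazard ratios must be positive")


def _order_statistic_median(draws: np.ndarray) -> float:
    """Median as an order statistic (lower of the two middle values when the
    count is even), so that it commutes exactly with any monotone transform."""
    return float(np.quantile(draws, 0.5, method="lower"))


def _percentiles(draws: np.ndarray):
    return (
        _order_statistic_median(draws),
        float(np.percentile(draws, 2.5)),
        float(np.percentile(draws, 97.5)),
    )


def hazard_ratio_table(fit: JointModelFit) -> HazardRatioTable:
    """Posterior median and central 95% interval of exp(coefficient) for each
    fixed covariate (gamma) and marker association (alpha).

    Because exp is monotone, median(exp(draws)) == exp(median(draws)); both
    are computed and asserted equal as a self-check.
    """
    rows = {}
    for name in [f"gamma.{c}" for c in COVARIATES] + [f"alpha.{m}" for m in MARKERS]:
        coef = fit.draw_array(name)
        hr_draws = np.exp(coef)
        med, lo, hi = _percentiles(hr_draws)
        med_of_log = float(np.exp(_order_statistic_median(coef)))
        if not np.isclose(med, med_of_log, rtol=1e-10, atol=0.0):
            raise AssertionError(
                "median(exp) and exp(median) disagree; draws are corrupted"
            )
        label = name.split(".", 1)[1]
        rows[label] = {"hr": med, "lower": lo, "upper": hi}
    return HazardRatioTable(pd.DataFrame(rows).T[["hr", "lower", "upper"]])


def coefficient_table(fit: JointModelFit) -> pd.DataFrame:
    """Longitudinal fixed-effect medians and 95% credible intervals, one
    block per marker (intercept, slope, covariate effects)."""
    rows = []
    for m in MARKERS:
        for label, name in (
            [("intercept", f"{m}.intercept"), ("slope", f"{m}.slope")]
            + [(c, f"{m}.beta.{c}") for c in COVARIATES]
        ):
            med, lo, hi = _percentiles(fit.draw_array(name))
            rows.append(
                {"marker": m, "coefficient": label, "median": med, "lower": lo, "upper": hi}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Individual trajectories


@dataclass
class TrajectorySummary:
    marker: str
    time_grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    median_slope: float

    def __post_init__(self) -> None:
        inside = (self.lower <= self.mean) & (self.mean <= self.upper)
        if not np.all(inside):
            raise AssertionError("pointwise interval must contain the mean")
        if not np.isfinite(self.median_slope):
            raise AssertionError("median slope must be finite")


def _marker_draw_parts(fit: JointModelFit, marker: str):
    layout = GlobalsLayout(fit.spline_spec.n_basis)
    sl = layout.marker_slices[marker]
    flat = fit.flat_g()
    b0 = flat[:, sl.start]
    b1 = flat[:, sl.start + 1]
    beta = flat[:, sl.start + 2 : sl.start + 7]
    return b0, b1, beta


def _re_cov_draws(fit: JointModelFit, marker: str):
    sda = fit.draw_array(f"{marker}.re_sd_intercept")
    sds = fit.draw_array(f"{marker}.re_sd_slope")
    rho = fit.draw_array(f"{marker}.re_corr")
    return sda, sds, rho


def _patient_index(fit: JointModelFit, patient_id) -> int:
    idx = np.flatnonzero(fit.patient_ids == patient_id)
    if idx.size == 0:
        raise KeyError(f"patient {patient_id!r} is not in the fitted cohort")
    return int(idx[0])


def _resolve_covariates(
    fit: JointModelFit, patient: Union[int, str, Mapping, pd.Series]
) -> np.ndarray:
    if isinstance(patient, (Mapping, pd.Series)):
        try:
            return np.array([float(patient[k]) for k in COVARIATES])
        except KeyError as exc:
            raise KeyError(f"unknown covariates: missing {exc.args[0]!r}") from None
    i = _patient_index(fit, patient)
    return fit.covariates[list(COVARIATES)].to_numpy(dtype=float)[i]


def predict_trajectory(
    fit: JointModelFit,
    patient: Union[int, str, Mapping, pd.Series],
    time_grid: Optional[np.ndarray] = None,
    marker: str = "FactorII",
) -> TrajectorySummary:
    """Posterior trajectory summary for one patient and marker.

    For an in-sample patient (referenced by id) the patient's random-effect
    draws are used, so sparse patients shrink toward the population curve.
    For a covariates mapping (a patient with no records) the mean curve is
    the population mean given those covariates, computed with the random
    effects at their exact zero mean, and the interval adds random-effect
    dispersion drawn from the posterior covariance.
    """
    if marker not in MARKERS:
        raise KeyError(f"unknown marker {marker!r}")
    if time_grid is None:
        time_grid = np.arange(0.0, 25.0 + 1e-9, 0.25)
    time_grid = np.asarray(time_grid, dtype=float)
    x = _resolve_covariates(fit, patient)
    b0, b1, beta = _marker_draw_parts(fit, marker)
    pop_int = b0 + beta @ x  # (S,)

    if isinstance(patient, (Mapping, pd.Series)):
        # no records: random effects at their prior (zero) mean per draw
        mean = (pop_int.mean() + b1.mean() * time_grid)
        rng = np.random.default_rng(np.random.SeedSequence([int(fit.engine.seed), 101]))
        sda, sds, rho = _re_cov_draws(fit, marker)
        z1 = rng.standard_normal(len(b0))
        z2 = rng.standard_normal(len(b0))
        a = sda * z1
        s = sds * (rho * z1 + np.sqrt(np.clip(1 - rho**2, 0.0, None)) * z2)
        eta = (pop_int + a)[:, None] + (b1 + s)[:, None] * time_grid[None, :]
        slope_draws = b1 + s
    else:
        i = _patient_index(fit, patient)
        if fit.u_draws is None:
            raise RuntimeError(
                "fit was run without stored random effects; refit with "
                "store_random_effects=True for in-sample prediction"
            )
        u = fit.u_draws[marker][:, :, i, :].reshape(-1, 2)
        eta = (pop_int + u[:, 0])[:, None] + (b1 + u[:, 1])[:, None] * time_grid[None, :]
        mean = eta.mean(axis=0)
        slope_draws = b1 + u[:, 1]

    lower = np.percentile(eta, 2.5, axis=0)
    upper = np.percentile(eta, 97.5, axis=0)
    if isinstance(patient, (Mapping, pd.Series)):
        # exact-zero-mean curve; keep the draw interval around it
        lower = np.minimum(lower, mean)
        upper = np.maximum(upper, mean)
    return TrajectorySummary(
        marker=marker,
        time_grid=time_grid,
        mean=np.asarray(mean, dtype=float),
        lower=lower,
        upper=upper,
        median_slope=float(np.median(slope_draws)),
    )


def individual_slope_distribution(fit: JointModelFit) -> pd.DataFrame:
    """Per-patient posterior median of the total slope (population plus
    individual deviation) for each marker; histogram-ready with the zero
    line as reference."""
    if fit.u_draws is None:
        raise RuntimeError("fit was run without stored random effects")
    layout = GlobalsLayout(fit.spline_spec.n_basis)
    frames = []
    for m in MARKERS:
        b1 = fit.flat_g()[:, layout.marker_slices[m].start + 1]
        s = fit.u_draws[m][:, :, :, 1].reshape(-1, len(fit.patient_ids))
        slopes = np.median(b1[:, None] + s, axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": fit.patient_ids,
                    "marker": m,
                    "median_slope": slopes,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["reference_line"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Dynamic conditional survival


def _cumhaz_draws(fit: JointModelFit, i: int, x: np.ndarray, t: float, n_nodes: int) -> np.ndarray:
    """H(t) per posterior draw for in-sample patient index i."""
    if t == 0.0:
        return np.zeros(fit.n_chains * fit.n_draws)
    layout = GlobalsLayout(fit.spline_spec.n_basis)
    flat = fit.flat_g()
    nodes, weights = gauss_legendre_nodes(t, n_nodes)
    B = bspline_basis(nodes, fit.spline_spec)  # (Q, K)
    lp = flat[:, layout.spline] @ B.T + (flat[:, layout.gamma] @ x)[:, None]  # (S, Q)
    for j, m in enumerate(MARKERS):
        sl = layout.marker_slices[m]
        b0 = flat[:, sl.start]
        b1 = flat[:, sl.start + 1]
        beta = flat[:, sl.start + 2 : sl.start + 7]
        u = fit.u_draws[m][:, :, i, :].reshape(-1, 2)
        A = b0 + beta @ x + u[:, 0]
        Bs = b1 + u[:, 1]
        alpha = flat[:, layout.alpha.start + j]
        lp = lp + alpha[:, None] * (A[:, None] + Bs[:, None] * nodes[None, :])
    return np.exp(lp) @ weights


def conditional_survival(
    fit: JointModelFit,
    patient,
    t_now: float,
    horizon: float,
    n_nodes: int = 15,
    return_draws: bool = False,
):
    """P(survive to t_now + horizon | alive at t_now) for an in-sample
    patient: posterior mean of exp(-[H(t_now+horizon) - H(t_now)]) over the
    patient's own trajectory draws."""
    if t_now < 0 or horizon <= 0:
        raise ValueError("t_now must be >= 0 and horizon > 0")
    lo, hi = fit.spline_spec.boundary
    if t_now + horizon > hi + 1e-9:
        raise SplineDomainError(
            f"prediction time {t_now + horizon} exceeds the spline boundary {hi}"
        )
    if fit.u_draws is None:
        raise RuntimeError("fit was run without stored random effects")
    i = _patient_index(fit, patient)
    x = fit.covariates[list(COVARIATES)].to_numpy(dtype=float)[i]
    H_now = _cumhaz_draws(fit, i, x, float(t_now), n_nodes)
    H_end = _cumhaz_draws(fit, i, x, float(t_now) + float(horizon), n_nodes)
    surv = np.exp(-(H_end - H_now))
    return surv if return_draws else float(np.mean(surv))


__all__ = [
    "HazardRatioTable",
    "TrajectorySummary",
    "hazard_ratio_table",
    "coefficient_table",
    "predict_trajectory",
    "individual_slope_distribution",
    "conditional_survival",
]
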