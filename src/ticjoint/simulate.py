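"""Synthetic trauma-cohort generator.

Generates cohorts with the statistical structure the joint model assumes:
fixed covariates drawn from the published cohort marginals, per-patient
random intercepts/slopes, biomarker measurements on a jittered blood-draw
schedule thinned by missingness, and death times drawn by inverse-transform
sampling from each patient's own time-varying hazard.  Every draw is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson

from .params import (
    COVARIATES,
    MARKERS,
    ConfigurationError,
    LongitudinalParams,
    MarkerParams,
    RandomEffects,
    SplineBasisSpec,
    SurvivalParams,
    re_covariance_matrix,
)
from .survival import bspline_basis

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class BinnedMarginal:
    """Probability distribution over half-open numeric bins [lo, hi)."""

    edges: Tuple[float, ...]  # len = n_bins + 1
    probs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.probs) + 1:
            raise ConfigurationError("edges must have one more entry than probs")
        if any(p < 0 for p in self.probs):
            raise ConfigurationError("bin probabilities must be >= 0")
        if abs(sum(self.probs) - 1.0) > 1e-6:
            raise ConfigurationError(
                f"bin probabilities must sum to 1, got {sum(self.probs):.6f}"
            )
        if list(self.edges) != sorted(self.edges):
            raise ConfigurationError("bin edges must be increasing")


@dataclass
class CovariateMarginals:
    """Marginal distributions of the fixed covariates (defaults: the
    published cohort of 891 severely injured trauma patients)."""

    male_fraction: float = 728 / 891
    tbi_fraction: float = 343 / 891
    penetrating_fraction: float = 385 / 891
    # Age bins; the open top bin (>= 80) is capped at 95 years.
    age: BinnedMarginal = field(
        default_factory=lambda: BinnedMarginal(
            edges=(15, 20, 30, 40, 50, 60, 70, 80, 95),
            probs=tuple(n / 891 for n in (58, 286, 170, 127, 115, 62, 42, 31)),
        )
    )
    # ISS bins; the open top bin (>= 60) is capped at 75 (the maximal score).
    iss: BinnedMarginal = field(
        default_factory=lambda: BinnedMarginal(
            edges=(0, 10, 20, 30, 40, 50, 60, 75),
            probs=tuple(n / 891 for n in (344, 168, 192, 108, 25, 38, 16)),
        )
    )

    def __post_init__(self) -> None:
        for name in ("male_fraction", "tbi_fraction", "penetrating_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


@dataclass
class CohortConfig:
    n_patients: int
    covariate_marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    schedule_hours: Tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 6.0, 12.0, 24.0)
    per_draw_missingness: float = 0.845
    jitter_sd: float = 0.25
    censor_time: float = 25.0
    true_longitudinal: LongitudinalParams = None
    true_survival: SurvivalParams = None
    re_covariance: Dict[str, np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not 0.0 <= self.per_draw_missingness <= 1.0:
            raise ConfigurationError("per_draw_missingness must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")
        if not self.censor_time > 0:
            raise ConfigurationError("censor_time must be > 0")
        if self.true_longitudinal is None:
            self.true_longitudinal = default_longitudinal_truth()
        if self.true_survival is None:
            self.true_survival = default_survival_truth()
        if self.re_covariance is None:
            self.re_covariance = default_re_covariance()
        for m in MARKERS:
            cov = np.asarray(self.re_covariance[m], dtype=float)
            if cov.shape != (2, 2):
                raise ConfigurationError(f"re_covariance[{m!r}] must be 2x2")
            _psd_factor(cov)  # raises if not PSD
            self.re_covariance[m] = cov


@dataclass
class SimulatedTruth:
    """Everything used to generate a cohort, for parameter-recovery tests."""

    config: CohortConfig
    random_effects: RandomEffects
    event_times: np.ndarray  # latent death times in hours; inf = beyond censoring


# ---------------------------------------------------------------------------
# Default generating truth (published posterior medians; residual sds and
# random-effect covariances are this package's own realistic choices, see
# docs/methods.md)

#: Level of the log baseline hazard at hour 0, calibrated once by
#: ``calibrate_event_rate`` so the default cohort's 25-hour death fraction
#: matches the published 6.8% early mortality.
BASELINE_LOG_LEVEL = -5.848125


def default_longitudinal_truth() -> LongitudinalParams:
    # covariate order: age, sex_male, iss, tbi, penetrating
    return LongitudinalParams(
        markers={
            "FactorII": MarkerParams(
                intercept=84.03,
                slope=-0.23,
                covariate_effects=np.array([-0.15, -1.58, -0.37, 2.65, -0.28]),
                sigma=12.0,
            ),
            "logDDimer": MarkerParams(
                intercept=-0.64,
                slope=0.011,
                covariate_effects=np.array([0.008, -0.20, 0.043, 0.44, -0.25]),
                sigma=1.0,
            ),
        }
    )


def default_survival_truth(baseline_log_level: float = BASELINE_LOG_LEVEL) -> SurvivalParams:
    spec = SplineBasisSpec()
    # Gently declining log baseline hazard (early bleeding deaths dominate);
    # coefficients at the Greville abscissae reproduce the line exactly.
    coeffs = baseline_log_level - 0.05 * spec.greville()
    return SurvivalParams(
        spline_coeffs=coeffs,
        gamma=np.log([1.02, 0.76, 1.03, 2.71, 6.08]),
        alpha=np.array([np.log(0.94), np.log(2.22)]),
        spline_spec=spec,
    )


def default_re_covariance() -> Dict[str, np.ndarray]:
    return {
        "FactorII": re_covariance_matrix(15.0, 0.30, -0.1),
        "logDDimer": re_covariance_matrix(1.30, 0.06, -0.1),
    }


def default_cohort_config(n_patients: int = 891, seed: int = 0, **kwargs) -> CohortConfig:
    return CohortConfig(n_patients=n_patients, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Sampling helpers


def _rng(config: CohortConfig, salt: int) -> np.random.Generator:
    # Distinct deterministic substream per operation.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def _psd_factor(cov: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Square root of a PSD matrix; raises ConfigurationError otherwise."""
    vals, vecs = np.linalg.eigh(cov)
    if np.any(vals < -tol * max(1.0, float(vals.max(initial=0.0)))):
        raise ConfigurationError(f"covariance is not positive semi-definite: {cov}")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _sample_binned(marg: BinnedMarginal, n: int, rng, integer: bool = False) -> np.ndarray:
    bins = rng.choice(len(marg.probs), size=n, p=marg.probs)
    lo = np.asarray(marg.edges)[bins]
    hi = np.asarray(marg.edges)[bins + 1]
    if integer:
        return rng.integers(lo.astype(int), hi.astype(int), size=n).astype(float)
    return rng.uniform(lo, hi)


def sample_fixed_covariates(config: CohortConfig) -> pd.DataFrame:
    """One row per patient, categorical/binned draws from the marginals.

    Age is continuous uniform within its bin; ISS integer uniform within its
    bin; covariates are drawn independently of each other (only marginals are
    published).  Deterministic given the config seed.
    """
    m = config.covariate_marginals
    n = config.n_patients
    rng = _rng(config, salt=1)
    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": _sample_binned(m.age, n, rng),
            "sex_male": (rng.random(n) < m.male_fraction).astype(int),
            "iss": _sample_binned(m.iss, n, rng, integer=True),
            "tbi": (rng.random(n) < m.tbi_fraction).astype(int),
            "penetrating": (rng.random(n) < m.penetrating_fraction).astype(int),
        }
    )
    return df


def sample_random_effects(config: CohortConfig) -> RandomEffects:
    """Zero-mean bivariate-normal (intercept, slope) pair per patient and
    marker, independent across markers."""
    rng = _rng(config, salt=2)
    n = config.n_patients
    effects = {}
    for m in MARKERS:
        L = _psd_factor(np.asarray(config.re_covariance[m], dtype=float))
        z = rng.standard_normal((n, 2))
        effects[m] = z @ L.T
    return RandomEffects(patient_ids=np.arange(n), effects=effects)


# ---------------------------------------------------------------------------
# Event-time simulation by inverse-transform sampling

#: Sentinel returned when the cumulative hazard never reaches -ln(u) within
#: the observation window (the patient survives past censoring).
BEYOND_CENSORING = np.inf


def _invert_cumhaz(
    grid: np.ndarray,
    H: np.ndarray,
    hazard_at: Callable[[np.ndarray, np.ndarray], np.ndarray],
    targets: np.ndarray,
) -> np.ndarray:
    """Solve H(T) = target per row by bracketing + Newton refinement.

    ``H`` is (n, G) cumulative hazard on the shared ``grid``;
    ``hazard_at(times, rows)`` evaluates each row's hazard at its own times.
    Rows whose total hazard falls short of the target get BEYOND_CENSORING.
    """
    n = H.shape[0]
    out = np.full(n, BEYOND_CENSORING)
    censored = H[:, -1] < targets
    active = np.flatnonzero(~censored)
    if active.size == 0:
        return out
    Ha, ta = H[active], targets[active]
    # bracketing cell
    k = np.argmax(Ha >= ta[:, None], axis=1)
    k = np.maximum(k, 1)
    t_lo, t_hi = grid[k - 1], grid[k]
    H_lo, H_hi = Ha[np.arange(active.size), k - 1], Ha[np.arange(active.size), k]
    dH = np.where(H_hi > H_lo, H_hi - H_lo, 1.0)
    T = t_lo + (ta - H_lo) * (t_hi - t_lo) / dH
    T = np.clip(T, t_lo, t_hi)
    # Newton refinement with local Gauss-Legendre integral from t_lo to T
    xi, w = np.polynomial.legendre.leggauss(8)
    for _ in range(3):
        half = 0.5 * (T - t_lo)
        nodes = t_lo[:, None] + half[:, None] * (xi[None, :] + 1.0)
        hv = hazard_at(nodes, active)
        H_T = H_lo + half * (hv @ w)
        hT = np.maximum(hazard_at(T[:, None], active)[:, 0], 1e-300)
        T = np.clip(T - (H_T - ta) / hT, t_lo, t_hi)
    out[active] = T
    return out


def simulate_event_time(
    linear_predictor_fn: Callable[[np.ndarray], np.ndarray],
    baseline_hazard: Callable[[np.ndarray], np.ndarray],
    u: Union[float, np.ndarray],
    censor_time: float = 25.0,
    grid_size: int = 2001,
) -> Union[float, np.ndarray]:
    """Inverse-transform event time: the T solving  int_0^T h(s) ds = -ln u.

    h(t) = baseline_hazard(t) * exp(linear_predictor_fn(t)).  Returns
    ``BEYOND_CENSORING`` (inf) when the cumulative hazard over
    [0, censor_time] is smaller than -ln(u).  ``u`` may be a scalar or array
    of uniform(0, 1] draws; u <= 0 (or > 1) is a domain error.
    """
    scalar = np.ndim(u) == 0
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u_arr <= 0) or np.any(u_arr > 1):
        raise ValueError("u must lie in (0, 1]")
    grid = np.linspace(0.0, censor_time, grid_size)

    def hfun(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.asarray(baseline_hazard(t), dtype=float) * np.exp(
            np.asarray(linear_predictor_fn(t), dtype=float)
        )

    h_grid = hfun(grid)
    if np.any(~np.isfinite(h_grid)) or np.any(h_grid < 0):
        raise ValueError("hazard must be finite and non-negative on the window")
    H = cumulative_simpson(h_grid, x=grid, initial=0.0)
    targets = -np.log(u_arr)
    out = np.where(targets == 0.0, 0.0, BEYOND_CENSORING)
    nonzero = targets > 0
    if np.any(nonzero):
        idx = np.flatnonzero(nonzero)
        res = _invert_cumhaz(
            grid,
            np.broadcast_to(H, (idx.size, grid_size)),
            lambda t, rows: hfun(t),
            targets[idx],
        )
        out = out.copy()
        out[idx] = res
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Cohort generation


def _patient_loglinear_hazard_terms(
    config: CohortConfig, covariates: pd.DataFrame, re: RandomEffects
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-patient constants (c, d) with  log h_i(t) = log h0(t) + c_i + d_i t.

    The current-value association makes the patient log hazard affine in t
    because the trajectories are affine in t.
    """
    sp = config.true_survival
    lp = config.true_longitudinal
    X = covariates[list(COVARIATES)].to_numpy(dtype=float)
    c = X @ sp.gamma
    d = np.zeros(len(covariates))
    for j, m in enumerate(MARKERS):
        mp = lp[m]
        a = re.effects[m][:, 0]
        s = re.effects[m][:, 1]
        c = c + sp.alpha[j] * (mp.intercept + a + X @ mp.covariate_effects)
        d = d + sp.alpha[j] * (mp.slope + s)
    return c, d


def _simulate_cohort_event_times(
    config: CohortConfig,
    covariates: pd.DataFrame,
    re: RandomEffects,
    u: np.ndarray,
    hazard_multiplier: float = 1.0,
    grid_size: int = 1001,
    chunk: int = 2000,
) -> np.ndarray:
    """Vectorized inverse-transform event times for a whole cohort.

    Processes patients in chunks to bound memory at large n.
    """
    n = len(covariates)
    if n == 0:
        return np.empty(0)
    c_all, d_all = _patient_loglinear_hazard_terms(config, covariates, re)
    c_all = c_all + np.log(hazard_multiplier)
    grid = np.linspace(0.0, config.censor_time, grid_size)
    sp = config.true_survival
    log_h0 = bspline_basis(grid, sp.spline_spec) @ sp.spline_coeffs

    out = np.empty(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        c, d = c_all[sl], d_all[sl]
        log_h = log_h0[None, :] + c[:, None] + d[:, None] * grid[None, :]
        H = cumulative_simpson(np.exp(log_h), x=grid, initial=0.0)

        def hazard_at(t: np.ndarray, rows: np.ndarray) -> np.ndarray:
            lb = bspline_basis(t.ravel(), sp.spline_spec) @ sp.spline_coeffs
            return np.exp(lb.reshape(t.shape) + c[rows, None] + d[rows, None] * t)

        out[sl] = _invert_cumhaz(grid, H, hazard_at, -np.log(u[sl]))
    return out


def generate_cohort(
    config: CohortConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Generate (covariates, longitudinal records, survival records, truth).

    Measurements happen at jittered schedule times, independently thinned per
    scheduled draw and marker, and stop at the patient's death or censoring
    time.  Biomarker values are Normal(eta, sigma) draws; log D-Dimer is
    generated directly on the log2 scale.
    """
    n = config.n_patients
    covariates = sample_fixed_covariates(config)
    re = sample_random_effects(config)
    rng = _rng(config, salt=3)

    u = rng.uniform(size=n) if n else np.empty(0)
    u = np.clip(u, np.finfo(float).tiny, 1.0)
    event = _simulate_cohort_event_times(config, covariates, re, u)
    died = event < config.censor_time
    T = np.where(died, event, config.censor_time)

    sched = np.asarray(config.schedule_hours, dtype=float)
    k = sched.size
    # jitter, keep non-negative, keep ordered
    times = sched[None, :] + rng.normal(0.0, config.jitter_sd, size=(n, k))
    times = np.sort(np.clip(times, 0.0, None), axis=1)
    keep = rng.random((n, k, len(MARKERS))) >= config.per_draw_missingness
    # a draw after death (or past the window) cannot happen
    alive = np.where(died[:, None], times[:, :] < T[:, None], times <= config.censor_time)
    keep &= alive[:, :, None]

    X = covariates[list(COVARIATES)].to_numpy(dtype=float)
    frames: List[pd.DataFrame] = []
    for j, m in enumerate(MARKERS):
        mp = config.true_longitudinal[m]
        pi, di = np.nonzero(keep[:, :, j])
        t_obs = times[pi, di]
        eta = (
            mp.intercept
            + re.effects[m][pi, 0]
            + (mp.slope + re.effects[m][pi, 1]) * t_obs
            + X[pi] @ mp.covariate_effects
        )
        y = eta + mp.sigma * rng.standard_normal(pi.size)
        frames.append(
            pd.DataFrame(
                {"patient_id": pi, "time_h": t_obs, "marker": m, "value": y}
            )
        )
    if frames:
        longitudinal = pd.concat(frames, ignore_index=True)
        longitudinal = longitudinal.sort_values(
            ["patient_id", "time_h", "marker"], kind="stable"
        ).reset_index(drop=True)
    else:
        longitudinal = pd.DataFrame(
            columns=["patient_id", "time_h", "marker", "value"]
        )

    survival = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "time_h": T,
            "death": died.astype(int),
        }
    )
    truth = SimulatedTruth(config=config, random_effects=re, event_times=event)
    return covariates, longitudinal, survival, truth


# ---------------------------------------------------------------------------
# Event-rate calibration


class CalibrationError(RuntimeError):
    """Raised when the target event rate is unattainable within bounds."""


def calibrate_event_rate(
    config: CohortConfig,
    target_rate: float,
    n_mc: int = 10000,
    tol: float = 0.002,
    log_mult_bounds: Tuple[float, float] = (-10.0, 10.0),
    max_iter: int = 60,
) -> float:
    """Constant multiplier on the baseline hazard scale such that the
    simulated 25-hour death fraction matches ``target_rate``.

    Uses common random numbers: because the cumulative hazard scales linearly
    with the multiplier, the simulated death fraction under a fixed set of
    uniform draws is a monotone step function of the multiplier, and
    bisection converges on it.
    """
    if not 0.0 < target_rate < 1.0:
        raise ConfigurationError("target_rate must be in (0, 1)")
    mc_config = CohortConfig(
        n_patients=n_mc,
        covariate_marginals=config.covariate_marginals,
        schedule_hours=config.schedule_hours,
        per_draw_missingness=config.per_draw_missingness,
        jitter_sd=config.jitter_sd,
        censor_time=config.censor_time,
        true_longitudinal=config.true_longitudinal,
        true_survival=config.true_survival,
        re_covariance=config.re_covariance,
        seed=config.seed,
    )
    covariates = sample_fixed_covariates(mc_config)
    re = sample_random_effects(mc_config)
    rng = _rng(mc_config, salt=4)
    u = np.clip(rng.uniform(size=n_mc), np.finfo(float).tiny, 1.0)
    targets = -np.log(u)

    c, d = _patient_loglinear_hazard_terms(mc_config, covariates, re)
    grid = np.linspace(0.0, config.censor_time, 1001)
    log_h0 = bspline_basis(grid, config.true_survival.spline_spec) @ (
        config.true_survival.spline_coeffs
    )
    H_total = np.empty(n_mc)
    for start in range(0, n_mc, 2000):
        sl = slice(start, min(start + 2000, n_mc))
        log_h = log_h0[None, :] + c[sl, None] + d[sl, None] * grid[None, :]
        H_total[sl] = cumulative_simpson(np.exp(log_h), x=grid, initial=0.0)[:, -1]

    def death_fraction(log_mult: float) -> float:
        return float(np.mean(np.exp(log_mult) * H_total >= targets))

    lo, hi = log_mult_bounds
    if death_fraction(lo) > target_rate or death_fraction(hi) < target_rate:
        raise CalibrationError(
            f"target rate {target_rate} unattainable with multiplier in "
            f"[e^{lo}, e^{hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = death_fraction(mid)
        if abs(f - target_rate) <= tol:
            return float(np.exp(mid))
        if f < target_rate:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


__all__ = [
    "BinnedMarginal",
    "CovariateMarginals",
    "CohortConfig",
    "SimulatedTruth",
    "BASELINE_LOG_LEVEL",
    "BEYOND_CENSORING",
    "CalibrationError",
    "default_longitudinal_truth",
    "default_survival_truth",
    "default_re_covariance",
    "default_cohort_config",
    "sample_fixed_covariates",
    "sample_random_effects",
    "simulate_event_time",
    "generate_cohort",
    "calibrate_event_rate",
]
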