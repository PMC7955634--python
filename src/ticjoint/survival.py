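"""Proportional-hazards survival submodel with a B-spline baseline hazard.

The hazard for patient i is

    h_i(t) = h0(t) * exp( gamma . x_i + sum_j alpha_j * eta_ij(t) )

where log h0(t) is a clamped B-spline on [0, censor_time] (positivity by
construction) and eta_ij(t) is the *expected* current value of marker j from
the longitudinal submodel, not the raw observation.
"""

from __future__ import annotations

from typing import Callable, Mapping, Union

import numpy as np
from scipy.interpolate import BSpline

from .params import ConfigurationError, MARKERS, SplineBasisSpec, SurvivalParams
from .longitudinal import covariate_vector


class SplineDomainError(ValueError):
    """Raised when a time falls outside the spline boundary interval."""


def bspline_basis(t: Union[float, np.ndarray], spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the clamped B-spline basis at times ``t``.

    Returns shape (n_basis,) for scalar ``t`` or (len(t), n_basis).  The
    basis is a partition of unity on the closed boundary interval; the right
    endpoint is included by convention.
    """
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = spec.boundary
    if np.any(arr < lo) or np.any(arr > hi):
        bad = arr[(arr < lo) | (arr > hi)]
        raise SplineDomainError(
            f"times outside spline boundary [{lo}, {hi}]: {bad[:10].tolist()}"
        )
    # Evaluate just inside the right endpoint so the closed-interval
    # convention holds (the basis is right-continuous elsewhere).
    eps = 1e-12 * max(1.0, abs(hi))
    clipped = np.minimum(arr, hi - eps)
    dm = BSpline.design_matrix(clipped, spec.knots, spec.degree).toarray()
    # Exactness at the right endpoint: the last basis function equals 1 there.
    at_hi = arr == hi
    if np.any(at_hi):
        row = np.zeros(spec.n_basis)
        row[-1] = 1.0
        dm[at_hi] = row
    return dm[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else dm


def log_baseline_hazard(t, params: SurvivalParams) -> Union[float, np.ndarray]:
    basis = bspline_basis(t, params.spline_spec)
    return basis @ params.spline_coeffs


def hazard(
    t: Union[float, np.ndarray],
    surv_params: SurvivalParams,
    eta_values: Mapping[str, Union[float, np.ndarray]],
    covariates: Mapping,
) -> Union[float, np.ndarray]:
    """Patient hazard rate per hour at time ``t``.

    ``eta_values`` maps each marker name to its expected value at ``t``
    (scalar, or array matching ``t``).
    """
    x = covariate_vector(covariates)
    lp = float(surv_params.gamma @ x)
    assoc = 0.0
    for j, marker in enumerate(MARKERS):
        assoc = assoc + surv_params.alpha[j] * np.asarray(eta_values[marker], dtype=float)
    out = np.exp(log_baseline_hazard(t, surv_params) + lp + assoc)
    return float(out) if np.ndim(out) == 0 else out


def gauss_legendre_nodes(t: float, n_nodes: int):
    """Nodes and weights of Gauss-Legendre quadrature rescaled to [0, t]."""
    if n_nodes < 1:
        raise ConfigurationError("n_nodes must be >= 1")
    xi, w = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * t * (xi + 1.0), 0.5 * t * w


def cumulative_hazard(
    t: float,
    surv_params: SurvivalParams,
    eta_fn: Callable[[np.ndarray], Mapping[str, np.ndarray]],
    covariates: Mapping,
    n_nodes: int = 15,
) -> float:
    """Integral of the hazard over [0, t] by Gauss-Legendre quadrature.

    ``eta_fn(times)`` returns {marker: eta values at those times}.
    """
    if t < 0:
        raise SplineDomainError("cumulative hazard requires t >= 0")
    if t == 0:
        return 0.0
    nodes, weights = gauss_legendre_nodes(t, n_nodes)
    h = hazard(nodes, surv_params, eta_fn(nodes), covariates)
    return float(weights @ np.atleast_1d(h))


def survival_prob(
    t: float,
    surv_params: SurvivalParams,
    eta_fn: Callable[[np.ndarray], Mapping[str, np.ndarray]],
    covariates: Mapping,
    n_nodes: int = 15,
) -> float:
    """S(t) = exp(-integral of hazard over [0, t]); non-increasing in t."""
    return float(np.exp(-cumulative_hazard(t, surv_params, eta_fn, covariates, n_nodes)))


__all__ = [
    "SplineDomainError",
    "bspline_basis",
    "log_baseline_hazard",
    "hazard",
    "gauss_legendre_nodes",
    "cumulative_hazard",
    "survival_prob",
]
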