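"""Shared parameter containers for the joint coagulopathy model.

The joint model has two longitudinal submodels (Factor II in % activity and
log2 D-Dimer in log2 ug/ml), each a linear mixed model with a random
intercept and random slope per patient, and a proportional-hazards survival
submodel whose log baseline hazard is a B-spline and whose linear predictor
includes the *expected* current biomarker values (current-value association).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np

#: Canonical marker order used everywhere (arrays indexed by marker follow it).
MARKERS: Tuple[str, str] = ("FactorII", "logDDimer")

#: Canonical fixed-covariate order: age (years), male sex, injury severity
#: score, traumatic brain injury, penetrating injury.  Indicators are coded 1
#: when the condition is present.
COVARIATES: Tuple[str, ...] = ("age", "sex_male", "iss", "tbi", "penetrating")

N_COVARIATES = len(COVARIATES)


class ConfigurationError(ValueError):
    """Raised for invalid model or generator configuration."""


@dataclass
class MarkerParams:
    """Fixed-effect parameters of one marker's trajectory submodel.

    eta_ij(t) = (intercept + a_i) + (slope + s_i) * t + covariate_effects . x_i
    with observation noise  y ~ Normal(eta, sigma).
    """

    intercept: float
    slope: float  # per hour
    covariate_effects: np.ndarray  # aligned with COVARIATES
    sigma: float  # residual sd, > 0

    def __post_init__(self) -> None:
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.covariate_effects.shape != (N_COVARIATES,):
            raise ConfigurationError(
                f"covariate_effects must have shape ({N_COVARIATES},), "
                f"got {self.covariate_effects.shape}"
            )
        if not self.sigma > 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class LongitudinalParams:
    """Per-marker fixed effects and residual sds, keyed by marker name."""

    markers: Dict[str, MarkerParams]

    def __getitem__(self, marker: str) -> MarkerParams:
        try:
            return self.markers[marker]
        except KeyError:
            raise KeyError(
                f"unknown marker {marker!r}; expected one of {MARKERS}"
            ) from None

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


@dataclass
class RandomEffects:
    """Per-patient (intercept, slope) deviations for each marker.

    ``effects[marker]`` is an (n_patients, 2) array aligned with
    ``patient_ids``; column 0 is the intercept deviation, column 1 the slope
    deviation (per hour).
    """

    patient_ids: np.ndarray
    effects: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        n = len(self.patient_ids)
        for m, arr in self.effects.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 2):
                raise ConfigurationError(
                    f"effects[{m!r}] must have shape ({n}, 2), got {arr.shape}"
                )
            self.effects[m] = arr

    @classmethod
    def zeros(cls, patient_ids: Sequence) -> "RandomEffects":
        n = len(patient_ids)
        return cls(
            patient_ids=np.asarray(patient_ids),
            effects={m: np.zeros((n, 2)) for m in MARKERS},
        )

    def lookup(self, patient_id, marker: str) -> np.ndarray:
        idx = np.flatnonzero(self.patient_ids == patient_id)
        if idx.size == 0:
            raise KeyError(f"unknown patient {patient_id!r}")
        return self.effects[marker][idx[0]]


@dataclass
class SplineBasisSpec:
    """B-spline basis for the log baseline hazard.

    ``order`` is the polynomial order (degree + 1); a 6-th order spline is
    piecewise quintic.  With no interior knots the basis has ``order``
    functions on the boundary interval, which keeps the baseline hazard
    flexible but parsimonious for a cohort with few events.
    """

    order: int = 6
    interior_knots: Tuple[float, ...] = ()
    boundary: Tuple[float, float] = (0.0, 25.0)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigurationError("spline order must be >= 1")
        lo, hi = self.boundary
        if not hi > lo:
            raise ConfigurationError("boundary must be an increasing interval")
        ks = tuple(float(k) for k in self.interior_knots)
        if any(not (lo < k < hi) for k in ks):
            raise ConfigurationError("interior knots must lie strictly inside boundary")
        if list(ks) != sorted(ks):
            raise ConfigurationError("interior knots must be sorted")
        self.interior_knots = ks

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def n_basis(self) -> int:
        return self.order + len(self.interior_knots)

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector."""
        lo, hi = self.boundary
        return np.concatenate(
            [np.full(self.order, lo), self.interior_knots, np.full(self.order, hi)]
        )

    def greville(self) -> np.ndarray:
        """Greville abscissae: coefficient locations at which a spline with
        coefficients equal to a linear function reproduces that function."""
        kn = self.knots
        p = self.degree
        if p == 0:
            return 0.5 * (kn[:-1] + kn[1:])[: self.n_basis]
        return np.array(
            [kn[i + 1 : i + 1 + p].mean() for i in range(self.n_basis)]
        )


@dataclass
class SurvivalParams:
    """Parameters of the proportional-hazards submodel.

    h_i(t) = h0(t) * exp(gamma . x_i + sum_j alpha_j * eta_ij(t)),
    log h0(t) = B(t) . spline_coeffs.
    """

    spline_coeffs: np.ndarray
    gamma: np.ndarray  # aligned with COVARIATES, log-hazard-ratio units
    alpha: np.ndarray  # aligned with MARKERS, log-HR per unit of eta
    spline_spec: SplineBasisSpec = field(default_factory=SplineBasisSpec)

    def __post_init__(self) -> None:
        self.spline_coeffs = np.asarray(self.spline_coeffs, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.gamma.shape != (N_COVARIATES,):
            raise ConfigurationError(f"gamma must have shape ({N_COVARIATES},)")
        if self.alpha.shape != (len(MARKERS),):
            raise ConfigurationError(f"alpha must have shape ({len(MARKERS)},)")
        if self.spline_coeffs.shape != (self.spline_spec.n_basis,):
            raise ConfigurationError(
                f"spline_coeffs length {self.spline_coeffs.shape} does not match "
                f"basis dimension {self.spline_spec.n_basis}"
            )

    def alpha_for(self, marker: str) -> float:
        return float(self.alpha[MARKERS.index(marker)])


@dataclass
class PriorSpec:
    """Weakly-informative prior scales (all configurable).

    Fixed-effect scales are interpreted on the standardized scale and
    autoscaled per marker by sd(y)/sd(x) at fit time (rstanarm convention);
    sigma and random-effect-sd half-Normal scales are multiplied by sd(y).
    """

    scale_intercept: float = 20.0
    scale_fixed: float = 2.5  # longitudinal covariate + slope effects
    scale_gamma: float = 2.5
    scale_alpha: float = 2.5
    scale_spline: float = 5.0
    scale_sigma: float = 10.0  # half-Normal, times sd(y) when autoscaling
    scale_re_sd: float = 10.0  # half-Normal, times sd(y) when autoscaling
    lkj_concentration: float = 1.0
    autoscale: bool = True

    def __post_init__(self) -> None:
        for name in (
            "scale_intercept", "scale_fixed", "scale_gamma", "scale_alpha",
            "scale_spline", "scale_sigma", "scale_re_sd", "lkj_concentration",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")


def re_covariance_matrix(sd_intercept: float, sd_slope: float, corr: float) -> np.ndarray:
    """2x2 covariance of (intercept, slope) deviations."""
    if sd_intercept < 0 or sd_slope < 0 or not -1.0 <= corr <= 1.0:
        raise ConfigurationError("invalid random-effect covariance parameters")
    c = corr * sd_intercept * sd_slope
    return np.array([[sd_intercept**2, c], [c, sd_slope**2]])


__all__ = [
    "MARKERS",
    "COVARIATES",
    "N_COVARIATES",
    "ConfigurationError",
    "MarkerParams",
    "LongitudinalParams",
    "RandomEffects",
    "SplineBasisSpec",
    "SurvivalParams",
    "PriorSpec",
    "re_covariance_matrix",
    "replace",
]
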