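"""Mixed-effects trajectory submodels for the coagulation biomarkers.

Each marker j follows

    y_ij(t) ~ Normal(eta_ij(t), sigma_j)
    eta_ij(t) = (b0_j + a_ij) + (b1_j + s_ij) * t + sum_k beta_jk * x_ik

with population intercept/slope (b0, b1), patient deviations (a, s) and
fixed covariates x (age, male sex, ISS, TBI, penetrating injury).
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .params import (
    COVARIATES,
    MARKERS,
    LongitudinalParams,
    RandomEffects,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


class DDimerDomainError(ValueError):
    """Raised for non-positive raw D-Dimer values (log2 undefined)."""


def log2_ddimer(raw: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Base-2 log transform applied to raw D-Dimer (ug/ml) on ingest.

    Raises :class:`DDimerDomainError` for values <= 0, reporting the
    offending entries.
    """
    arr = np.asarray(raw, dtype=float)
    bad = ~(arr > 0)
    if np.any(bad):
        offenders = np.atleast_1d(arr)[np.atleast_1d(bad)]
        raise DDimerDomainError(
            f"D-Dimer values must be > 0 ug/ml for the log2 transform; "
            f"offending values: {offenders[:10].tolist()}"
        )
    out = np.log2(arr)
    return float(out) if np.isscalar(raw) else out


def covariate_vector(covariates: Union[Mapping, pd.Series]) -> np.ndarray:
    """Extract the x_ik vector in canonical COVARIATES order."""
    try:
        return np.array([float(covariates[k]) for k in COVARIATES])
    except KeyError as exc:
        raise KeyError(f"missing covariate {exc.args[0]!r}") from None


def linear_predictor(
    params: LongitudinalParams,
    random_effects: RandomEffects,
    covariates: Union[Mapping, pd.Series],
    t: Union[float, np.ndarray],
    marker: str,
    patient_id=None,
) -> Union[float, np.ndarray]:
    """Expected marker value eta_ij(t) for one patient.

    ``covariates`` holds the patient's fixed covariates (and, if
    ``patient_id`` is not given, a ``patient_id`` entry used to look up the
    random effects).
    """
    if marker not in MARKERS:
        raise KeyError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    mp = params[marker]
    if patient_id is None:
        patient_id = covariates["patient_id"]
    a, s = random_effects.lookup(patient_id, marker)
    x = covariate_vector(covariates)
    t = np.asarray(t, dtype=float)
    eta = (mp.intercept + a) + (mp.slope + s) * t + float(mp.covariate_effects @ x)
    return float(eta) if eta.ndim == 0 else eta


def longitudinal_loglik(
    params: LongitudinalParams,
    random_effects: RandomEffects,
    records: pd.DataFrame,
    covariates: pd.DataFrame,
) -> float:
    """Sum of Gaussian log-densities of all records under the submodels.

    ``records`` is long-format with columns (patient_id, time_h, marker,
    value); ``covariates`` one row per patient with the COVARIATES columns.
    Invariant to record order.
    """
    if len(records) == 0:
        return 0.0
    cov = covariates.set_index("patient_id")
    total = 0.0
    for marker, grp in records.groupby("marker", sort=False):
        mp = params[marker]
        pid = grp["patient_id"].to_numpy()
        pos = random_effects.patient_ids
        order = {p: i for i, p in enumerate(pos)}
        idx = np.array([order[p] for p in pid])
        u = random_effects.effects[marker][idx]
        x = cov.loc[pid, list(COVARIATES)].to_numpy(dtype=float)
        t = grp["time_h"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        eta = (mp.intercept + u[:, 0]) + (mp.slope + u[:, 1]) * t + x @ mp.covariate_effects
        z = (y - eta) / mp.sigma
        total += float(np.sum(-0.5 * z**2 - np.log(mp.sigma) - 0.5 * _LOG_2PI))
    return total


__all__ = [
    "DDimerDomainError",
    "log2_ddimer",
    "covariate_vector",
    "linear_predictor",
    "longitudinal_loglik",
]
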