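"""In-memory cohort container shared by the fitting and reporting layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import COVARIATES


class CohortValidationError(ValueError):
    """Raised when cohort tables violate the expected layout or invariants."""


@dataclass
class CohortData:
    """A validated cohort: fixed covariates, long-format biomarker records
    (log2 D-Dimer already applied), and one-row-per-patient survival records.
    """

    covariates: pd.DataFrame  # patient_id + COVARIATES
    longitudinal: pd.DataFrame  # patient_id, time_h, marker, value
    survival: pd.DataFrame  # patient_id, time_h, death

    def __post_init__(self) -> None:
        for col in ("patient_id", *COVARIATES):
            if col not in self.covariates.columns:
                raise CohortValidationError(f"covariates table missing column {col!r}")
        for col in ("patient_id", "time_h", "marker", "value"):
            if col not in self.longitudinal.columns:
                raise CohortValidationError(f"longitudinal table missing column {col!r}")
        for col in ("patient_id", "time_h", "death"):
            if col not in self.survival.columns:
                raise CohortValidationError(f"survival table missing column {col!r}")
        if self.covariates["patient_id"].duplicated().any():
            raise CohortValidationError("duplicate patient_id in covariates table")
        if self.survival["patient_id"].duplicated().any():
            raise CohortValidationError("duplicate patient_id in survival table")

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    @property
    def n_events(self) -> int:
        return int(self.survival["death"].sum())

    @property
    def patient_ids(self) -> np.ndarray:
        return self.covariates["patient_id"].to_numpy()

    def records_for(self, patient_id, marker: str | None = None) -> pd.DataFrame:
        sel = self.longitudinal["patient_id"] == patient_id
        if marker is not None:
            sel &= self.longitudinal["marker"] == marker
        return self.longitudinal[sel]


__all__ = ["CohortData", "CohortValidationError"]
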