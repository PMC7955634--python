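"""File formats, preprocessing filters and run configuration.

Canonical on-disk format: comma-delimited text with a header row.

* ``covariates.csv`` — patient_id, age, sex_male, iss, tbi, penetrating
* ``longitudinal.csv`` — patient_id, time_h, marker, value with marker in
  {FactorII, DDimer}; D-Dimer is stored raw (ug/ml, clinically readable) and
  log2-transformed on ingest
* ``survival.csv`` — patient_id, time_h, death

Times are hours from admission; missingness is expressed by absent rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .data import CohortData, CohortValidationError
from .inference import EngineConfig, JointModelFit
from .longitudinal import log2_ddimer
from .params import COVARIATES, MARKERS, PriorSpec, SplineBasisSpec
from .simulate import SimulatedTruth

logger = logging.getLogger("ticjoint")

#: on-disk marker names and their in-memory counterparts
_DISK_TO_MEMORY = {"FactorII": "FactorII", "DDimer": "logDDimer"}
_MEMORY_TO_DISK = {v: k for k, v in _DISK_TO_MEMORY.items()}


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Pipeline configuration (parsed from a YAML file with sections)."""

    covariates_path: str = "covariates.csv"
    longitudinal_path: str = "longitudinal.csv"
    survival_path: str = "survival.csv"
    censor_time: float = 25.0
    spline: SplineBasisSpec = field(default_factory=SplineBasisSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    engine: EngineConfig = field(default_factory=EngineConfig)
    simulate: Dict = field(default_factory=dict)  # CohortConfig overrides
    output_dir: str = "ticjoint_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("covariates_path", "longitudinal_path", "survival_path",
                    "censor_time", "output_dir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "spline" in raw:
            sp = raw["spline"]
            cfg.spline = SplineBasisSpec(
                order=sp.get("order", 6),
                interior_knots=tuple(sp.get("interior_knots", ())),
                boundary=tuple(sp.get("boundary", (0.0, cfg.censor_time))),
            )
        if "priors" in raw:
            cfg.priors = PriorSpec(**raw["priors"])
        if "engine" in raw:
            cfg.engine = EngineConfig(**raw["engine"])
        cfg.simulate = raw.get("simulate", {})
        return cfg

    def to_yaml(self, path) -> None:
        out = {
            "covariates_path": self.covariates_path,
            "longitudinal_path": self.longitudinal_path,
            "survival_path": self.survival_path,
            "censor_time": self.censor_time,
            "output_dir": self.output_dir,
            "spline": {
                "order": self.spline.order,
                "interior_knots": list(self.spline.interior_knots),
                "boundary": list(self.spline.boundary),
            },
            "priors": dataclasses.asdict(self.priors),
            "engine": dataclasses.asdict(self.engine),
            "simulate": self.simulate,
        }
        Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


# ---------------------------------------------------------------------------
# Reading and writing cohorts


def _require_columns(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{table} is missing columns {missing}")


def _require_numeric(df: pd.DataFrame, cols, table: str) -> pd.DataFrame:
    for c in cols:
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[parsed.isna() & df[c].notna()].tolist()
        if parsed.isna().any():
            bad = df.index[parsed.isna()].tolist()
            raise CohortValidationError(
                f"{table}: non-numeric or missing values in column {c!r} "
                f"at rows {bad[:10]}"
            )
        df[c] = parsed
    return df


def read_cohort(
    covariates_path,
    longitudinal_path,
    survival_path,
    censor_time: float = 25.0,
) -> CohortData:
    """Read and validate the three delimited tables; transforms raw D-Dimer
    to log2 on ingest.  Raises :class:`CohortValidationError` with offending
    row numbers on layout or unit violations."""
    cov = pd.read_csv(covariates_path)
    rec = pd.read_csv(longitudinal_path)
    surv = pd.read_csv(survival_path)

    _require_columns(cov, ("patient_id", *COVARIATES), "covariates table")
    _require_columns(rec, ("patient_id", "time_h", "marker", "value"), "longitudinal table")
    _require_columns(surv, ("patient_id", "time_h", "death"), "survival table")
    cov = _require_numeric(cov, COVARIATES, "covariates table")
    rec = _require_numeric(rec, ("time_h", "value"), "longitudinal table")
    surv = _require_numeric(surv, ("time_h", "death"), "survival table")

    unknown = ~rec["marker"].isin(_DISK_TO_MEMORY)
    if unknown.any():
        rows = rec.index[unknown].tolist()
        names = sorted(rec.loc[unknown, "marker"].unique().tolist())
        raise CohortValidationError(
            f"longitudinal table: unknown marker names {names} at rows {rows[:10]} "
            f"(expected {sorted(_DISK_TO_MEMORY)})"
        )
    dup = rec.duplicated(subset=["patient_id", "marker", "time_h"], keep=False)
    if dup.any():
        raise CohortValidationError(
            f"longitudinal table: duplicate (patient, marker, time) rows at "
            f"{rec.index[dup].tolist()[:10]}"
        )
    if (rec["time_h"] < 0).any():
        rows = rec.index[rec["time_h"] < 0].tolist()
        raise CohortValidationError(f"longitudinal table: negative times at rows {rows[:10]}")
    late = rec["time_h"] > censor_time
    if late.any():
        raise CohortValidationError(
            f"longitudinal table: measurement times beyond the {censor_time} h "
            f"window at rows {rec.index[late].tolist()[:10]}"
        )
    known = set(cov["patient_id"])
    for name, df in (("longitudinal", rec), ("survival", surv)):
        orphan = ~df["patient_id"].isin(known)
        if orphan.any():
            raise CohortValidationError(
                f"{name} table: unknown patient ids at rows "
                f"{df.index[orphan].tolist()[:10]}"
            )
    if not surv["death"].isin((0, 1)).all():
        rows = surv.index[~surv["death"].isin((0, 1))].tolist()
        raise CohortValidationError(f"survival table: death must be 0/1 at rows {rows[:10]}")
    if (surv["time_h"] <= 0).any():
        rows = surv.index[surv["time_h"] <= 0].tolist()
        raise CohortValidationError(f"survival table: times must be > 0 at rows {rows[:10]}")

    rec = rec.copy()
    is_dd = rec["marker"] == "DDimer"
    if is_dd.any():
        raw = rec.loc[is_dd, "value"]
        nonpos = raw <= 0
        if nonpos.any():
            raise CohortValidationError(
                f"longitudinal table: non-positive D-Dimer values at rows "
                f"{raw.index[nonpos].tolist()[:10]}"
            )
        rec.loc[is_dd, "value"] = log2_ddimer(raw.to_numpy(dtype=float))
    rec["marker"] = rec["marker"].map(_DISK_TO_MEMORY)
    return CohortData(covariates=cov, longitudinal=rec, survival=surv)


def write_cohort(
    out_dir,
    data: CohortData,
    truth: Optional[SimulatedTruth] = None,
) -> Dict[str, Path]:
    """Write the three delimited tables (D-Dimer back-transformed to raw
    ug/ml) plus, for synthetic cohorts, a truth sidecar never read by the
    fitting path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": out / "covariates.csv",
        "longitudinal": out / "longitudinal.csv",
        "survival": out / "survival.csv",
    }
    data.covariates.to_csv(paths["covariates"], index=False)
    rec = data.longitudinal.copy()
    is_dd = rec["marker"] == "logDDimer"
    rec.loc[is_dd, "value"] = np.exp2(rec.loc[is_dd, "value"])
    rec["marker"] = rec["marker"].map(_MEMORY_TO_DISK)
    rec.to_csv(paths["longitudinal"], index=False)
    data.survival.to_csv(paths["survival"], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(_truth_to_dict(truth), indent=1))
    return paths


def _truth_to_dict(truth: SimulatedTruth) -> Dict:
    cfg = truth.config
    return {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "censor_time": cfg.censor_time,
        "per_draw_missingness": cfg.per_draw_missingness,
        "jitter_sd": cfg.jitter_sd,
        "schedule_hours": list(cfg.schedule_hours),
        "longitudinal": {
            m: {
                "intercept": cfg.true_longitudinal[m].intercept,
                "slope": cfg.true_longitudinal[m].slope,
                "covariate_effects": cfg.true_longitudinal[m].covariate_effects.tolist(),
                "sigma": cfg.true_longitudinal[m].sigma,
            }
            for m in MARKERS
        },
        "survival": {
            "spline_coeffs": cfg.true_survival.spline_coeffs.tolist(),
            "gamma": cfg.true_survival.gamma.tolist(),
            "alpha": cfg.true_survival.alpha.tolist(),
        },
        "re_covariance": {m: np.asarray(cfg.re_covariance[m]).tolist() for m in MARKERS},
        "random_effects": {
            m: truth.random_effects.effects[m].tolist() for m in MARKERS
        },
        "event_times": [
            None if not np.isfinite(t) else float(t) for t in truth.event_times
        ],
    }


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    excluded_no_records: List
    n_deaths_capped: int

    def __str__(self) -> str:
        return (
            f"{self.n_input} patients in; {len(self.excluded_no_records)} excluded "
            f"with no biomarker records; {self.n_deaths_capped} deaths beyond the "
            f"window recoded as censored; {self.n_retained} retained"
        )


def preprocess(data: CohortData, censor_time: float = 25.0) -> Tuple[CohortData, ExclusionReport]:
    """Apply the cohort filters: drop patients with zero marker records and
    cap follow-up at ``censor_time`` (later deaths become censored)."""
    with_records = set(data.longitudinal["patient_id"])
    keep = data.covariates["patient_id"].isin(with_records)
    excluded = data.covariates.loc[~keep, "patient_id"].tolist()

    cov = data.covariates[keep].reset_index(drop=True)
    surv = data.survival[data.survival["patient_id"].isin(with_records)].reset_index(drop=True)
    late = surv["time_h"] > censor_time
    capped_deaths = int((late & (surv["death"] == 1)).sum())
    surv = surv.copy()
    surv.loc[late, "death"] = 0
    surv.loc[late, "time_h"] = censor_time
    rec = data.longitudinal[data.longitudinal["patient_id"].isin(with_records)].reset_index(
        drop=True
    )

    out = CohortData(covariates=cov, longitudinal=rec, survival=surv)
    if out.n_patients == 0:
        raise CohortValidationError("empty cohort after preprocessing")
    report = ExclusionReport(
        n_input=data.n_patients,
        n_retained=out.n_patients,
        excluded_no_records=excluded,
        n_deaths_capped=capped_deaths,
    )
    logger.info("preprocess: %s", report)
    return out, report


def cohort_characteristics(data: CohortData) -> pd.DataFrame:
    """Cohort summary table (counts and percentages) in the style of a
    clinical Table 1."""
    n = data.n_patients
    cov = data.covariates
    deaths = data.n_events

    def frac(k: int) -> str:
        return f"{k} ({100.0 * k / n:.1f}%)" if n else "0"

    rows = [
        ("Total number of individuals", str(n)),
        ("Death within window, n (%)", frac(deaths)),
        ("Male, n (%)", frac(int(cov["sex_male"].sum()))),
        ("Traumatic brain injury, n (%)", frac(int(cov["tbi"].sum()))),
        ("Penetrating injury, n (%)", frac(int(cov["penetrating"].sum()))),
        ("Age, median (IQR)", _median_iqr(cov["age"])),
        ("Injury severity score, median (IQR)", _median_iqr(cov["iss"])),
        ("Longitudinal observations", str(len(data.longitudinal))),
        (
            "Observations per patient, mean",
            f"{len(data.longitudinal) / n:.2f}" if n else "0",
        ),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "estimate"])


def _median_iqr(x: pd.Series) -> str:
    return f"{x.median():.0f} ({x.quantile(0.25):.0f}-{x.quantile(0.75):.0f})"


# ---------------------------------------------------------------------------
# Fit persistence (for the CLI pipeline)


def save_fit(out_dir, fit_result: JointModelFit) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit_result.summary().to_csv(out / "summary.csv", index=False)
    chains, ndraws, dim = fit_result.g_draws.shape
    np.save(out / "g_draws.npy", fit_result.g_draws)
    if fit_result.u_draws is not None:
        np.savez(out / "u_draws.npz", **fit_result.u_draws)
    fit_result.covariates.to_csv(out / "fit_covariates.csv", index=False)
    if fit_result.data is not None:
        write_cohort(out / "fit_data", fit_result.data)
    meta = {
        "chains": chains,
        "draws": ndraws,
        "dim": dim,
        "engine": dataclasses.asdict(fit_result.engine),
        "spline": {
            "order": fit_result.spline_spec.order,
            "interior_knots": list(fit_result.spline_spec.interior_knots),
            "boundary": list(fit_result.spline_spec.boundary),
        },
        "patient_ids": fit_result.patient_ids.tolist(),
        "converged": bool(fit_result.diagnostics_report.converged),
        "warnings": fit_result.diagnostics_report.warnings,
    }
    (out / "fit_meta.json").write_text(json.dumps(meta, indent=1))
    fit_result.diagnostics_report.rhat.rename("rhat").to_frame().join(
        fit_result.diagnostics_report.ess.rename("ess")
    ).to_csv(out / "diagnostics.csv", index_label="parameter")


def load_fit(fit_dir) -> JointModelFit:
    from .inference import DiagnosticsReport, GlobalsLayout, _named_draws

    d = Path(fit_dir)
    meta = json.loads((d / "fit_meta.json").read_text())
    spline = SplineBasisSpec(
        order=meta["spline"]["order"],
        interior_knots=tuple(meta["spline"]["interior_knots"]),
        boundary=tuple(meta["spline"]["boundary"]),
    )
    g_draws = np.load(d / "g_draws.npy")
    u_path = d / "u_draws.npz"
    u_draws = None
    if u_path.exists():
        with np.load(u_path) as z:
            u_draws = {m: z[m] for m in z.files}
    covariates = pd.read_csv(d / "fit_covariates.csv")
    data = None
    data_dir = d / "fit_data"
    if data_dir.exists():
        data = read_cohort(
            data_dir / "covariates.csv",
            data_dir / "longitudinal.csv",
            data_dir / "survival.csv",
            censor_time=float(meta["spline"]["boundary"][1]),
        )
    diag_df = pd.read_csv(d / "diagnostics.csv", index_col="parameter")
    layout = GlobalsLayout(spline.n_basis)
    engine = EngineConfig(**meta["engine"])
    return JointModelFit(
        draws=_named_draws(g_draws, layout),
        g_draws=g_draws,
        u_draws=u_draws,
        mode_params=layout.unpack(np.median(g_draws.reshape(-1, g_draws.shape[-1]), axis=0), spline),
        u_hat=None,
        patient_ids=np.asarray(meta["patient_ids"]),
        covariates=covariates,
        data=data,
        spline_spec=spline,
        engine=engine,
        diagnostics_report=DiagnosticsReport(
            rhat=diag_df["rhat"],
            ess=diag_df["ess"],
            converged=bool(meta["converged"]),
            warnings=list(meta["warnings"]),
        ),
        runtime_s=0.0,
    )


__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "preprocess",
    "ExclusionReport",
    "cohort_characteristics",
    "save_fit",
    "load_fit",
]
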