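"""Configuration, file I/O and pipeline orchestration.

File dialects
-------------
* schedule CSV: columns ``age,qx[,exposure,deaths]``, header row, period
  decimal separator, UTF-8; comment lines start with ``#``.
* life-table CSV: columns ``age,qx,lx,dx,ex``.
* fit / burden reports: JSON.

Every file written here carries the run's configuration hash (first line
``# hpburden-config: <hash>`` for CSV, a ``config_hash`` key for JSON) so an
artifact can always be traced to the exact configuration that produced it.

The run configuration is a flat, typed key-value document (YAML); unknown
keys are rejected so a misspelled ``retirement_age`` cannot silently revert
to the default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import burden_metrics, model_fitting
from .burden_metrics import BurdenReport, DelayResult, EconomicParams, burden_report, delay_sweep
from .hp_mortality import DAYS_PER_YEAR, HPParameters, PolicyScenario, policy_delay
from .life_table import CohortTrajectory, MortalitySchedule, propagate_cohort, to_quarterly_grid
from .model_fitting import BootstrapResult, FitResult, bootstrap_fit, fit_hp
from .synthetic_data import GRID_STEPS, SyntheticConfig, simulate_schedule

__all__ = [
    "ValidationError",
    "NumericalError",
    "RunConfig",
    "PipelineResult",
    "read_schedule",
    "write_schedule",
    "write_life_table",
    "read_params_csv",
    "write_params_csv",
    "run_pipeline",
]


class ValidationError(ValueError):
    """Bad inputs or configuration (CLI exit code 2)."""


class NumericalError(RuntimeError):
    """A computation failed numerically (CLI exit code 3)."""


# ------------------------------------------------------------------ I/O

def read_schedule(path) -> MortalitySchedule:
    """Read and validate a mortality schedule CSV (``age,qx[,exposure,deaths]``)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"schedule file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    missing = {"age", "qx"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    problems = []
    for row in frame.itertuples():
        if not np.isfinite(row.age) or row.age <= 0:
            problems.append(f"row {row.Index}: age {row.age!r} not a positive number")
        if not np.isfinite(row.qx) or not (0 < row.qx < 1):
            problems.append(f"row {row.Index}: qx {row.qx!r} outside (0, 1)")
        if "deaths" in frame.columns and "exposure" in frame.columns:
            if row.deaths > row.exposure:
                problems.append(f"row {row.Index}: deaths {row.deaths} exceed exposure {row.exposure}")
    duplicated = frame["age"].duplicated()
    if duplicated.any():
        for i in frame.index[duplicated]:
            problems.append(f"row {i}: duplicate age {frame.at[i, 'age']}")
    if problems:
        raise ValidationError(f"{path}: invalid schedule:\n  " + "\n  ".join(problems))
    try:
        return MortalitySchedule.from_frame(frame)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _csv_header_comment(config_hash: Optional[str]) -> str:
    return f"# hpburden-config: {config_hash or 'unconfigured'}\n"


def write_schedule(schedule: MortalitySchedule, path, config_hash: Optional[str] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_csv_header_comment(config_hash))
        schedule.to_frame().to_csv(handle, index=False)
    return path


def write_life_table(trajectory: CohortTrajectory, path, config_hash: Optional[str] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_csv_header_comment(config_hash))
        trajectory.to_frame().to_csv(handle, index=False)
    return path


def read_life_table(path) -> CohortTrajectory:
    """Read a life-table CSV back into a trajectory (mode recorded as metadata is lost)."""
    frame = pd.read_csv(Path(path), comment="#")
    for column in ("age", "lx", "dx"):
        if column not in frame.columns:
            raise ValidationError(f"{path}: missing life-table column {column!r}")
    ages = frame["age"].to_numpy(float)
    steps = np.diff(ages)
    step = float(steps[0]) if len(steps) else 1.0
    ex = frame["ex"].to_numpy(float) if "ex" in frame.columns else None
    if ex is not None and np.all(np.isnan(ex)):
        ex = None
    return CohortTrajectory(
        ages=ages,
        lx=frame["lx"].to_numpy(float),
        dx=frame["dx"].to_numpy(float),
        step=round(step, 6),
        mode="replication",
        ex=ex,
    )


def write_params_csv(params: HPParameters, path, config_hash: Optional[str] = None) -> Path:
    """Write the eight parameters as one CSV row with header A..H."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_csv_header_comment(config_hash))
        pd.DataFrame([params.to_dict()]).to_csv(handle, index=False)
    return path


def read_params_csv(path) -> HPParameters:
    frame = pd.read_csv(Path(path), comment="#")
    if len(frame) != 1:
        raise ValidationError(f"{path}: expected exactly one parameter row, got {len(frame)}")
    try:
        return HPParameters.from_dict(frame.iloc[0].to_dict())
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _write_json(payload: dict, path, config_hash: Optional[str]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": config_hash or "unconfigured", **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8")
    return path


# ----------------------------------------------------------------- config

_CONFIG_DEFAULTS = dict(
    schedule_csv=None,
    output_dir="hpburden_out",
    loss="relative_sse",
    mode="replication",
    grid="quarterly",
    gdp_per_capita=17_347.0,
    retirement_age=67.0,
    currency_label="EUR",
    age_of_diagnosis=45.0,
    delay_years=0.0,
    delay_days=None,
    health_policy=0,
    l0=160_000.0,
    age_start=45.0,
    age_end=86.0,
    exposure_per_age=10_000.0,
    noise_free=False,
    bootstrap_replicates=0,
    seed=0,
    delays=(),
    mean_age_rule="death_weighted",
    verbosity=1,
)


@dataclass(frozen=True)
class RunConfig:
    """Flat pipeline configuration; defaults reproduce the reference setup
    (reference-parameter starting values, l0 = 160,000, retirement at 67,
    GDP per capita 17,347, bands 45-84, quarterly replication mode)."""

    schedule_csv: Optional[str] = None
    output_dir: str = "hpburden_out"
    loss: str = "relative_sse"
    mode: str = "replication"
    grid: str = "quarterly"
    gdp_per_capita: float = 17_347.0
    retirement_age: float = 67.0
    currency_label: str = "EUR"
    age_of_diagnosis: float = 45.0
    delay_years: float = 0.0
    delay_days: Optional[float] = None
    health_policy: int = 0
    l0: float = 160_000.0
    age_start: float = 45.0
    age_end: float = 86.0
    exposure_per_age: float = 10_000.0
    noise_free: bool = False
    bootstrap_replicates: int = 0
    seed: int = 0
    delays: Sequence[float] = ()
    mean_age_rule: str = "death_weighted"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.delay_days is not None and self.delay_years:
            raise ValidationError("give delay_days or delay_years, not both")
        if self.loss not in model_fitting.LOSS_FUNCTIONS:
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.mode not in ("replication", "actuarial"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.grid not in GRID_STEPS:
            raise ValidationError(f"unknown grid {self.grid!r}")
        if self.schedule_csv is not None and not Path(self.schedule_csv).exists():
            raise ValidationError(f"schedule_csv does not exist: {self.schedule_csv}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a flat key-value mapping")
        unknown = set(raw) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @property
    def scenario(self) -> PolicyScenario:
        if self.delay_days is not None:
            return PolicyScenario.from_days(self.age_of_diagnosis, self.delay_days, self.health_policy)
        return PolicyScenario(self.age_of_diagnosis, self.delay_years, self.health_policy)

    @property
    def economics(self) -> EconomicParams:
        return EconomicParams(self.gdp_per_capita, self.retirement_age, self.currency_label)

    @property
    def propagation_step(self) -> float:
        return 1.0 if self.grid == "annual" else 0.25

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(self).items()}
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
        return digest[:12]


# --------------------------------------------------------------- pipeline

@dataclass(frozen=True)
class PipelineResult:
    """All in-memory results of one orchestrated run, plus artifact paths."""

    config: RunConfig
    schedule: MortalitySchedule
    fit: FitResult
    trajectory: CohortTrajectory
    report: BurdenReport
    sweep: List[DelayResult]
    bootstrap: Optional[BootstrapResult]
    artifacts: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run fit -> propagate -> band -> YLL/YPPLL/CPL (-> delay sweep).

    Artifacts written to ``config.output_dir``: the (simulated or echoed)
    schedule, fit report JSON, fitted-parameter CSV, life-table CSV, burden
    JSON + CSV, sweep CSV when delays are configured, and a plain-text run
    log.  Any stage failure aborts with the stage name; the log records the
    partial run flagged incomplete.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict = {}
    log_lines = [
        f"hpburden run, config hash {chash}",
        f"seed: {config.seed}",
        f"mode: {config.mode}",
        f"loss: {config.loss}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
    ]
    stage = "load-schedule"
    try:
        if config.schedule_csv is not None:
            schedule = read_schedule(config.schedule_csv)
        else:
            schedule = simulate_schedule(SyntheticConfig(
                age_start=config.age_start,
                age_end=config.age_end,
                grid=config.grid,
                exposure_per_age=config.exposure_per_age,
                l0=config.l0,
                seed=config.seed,
                noise_free=config.noise_free,
            ))
        if config.grid == "daily":
            # fine schedules are thinned to the four quarter points per year
            schedule = to_quarterly_grid(schedule)
        artifacts["schedule"] = write_schedule(schedule, out / "schedule.csv", chash)
        log_lines.append(f"schedule: {len(schedule)} ages on [{schedule.ages[0]}, {schedule.ages[-1]}]")

        stage = "fit"
        fit = fit_hp(schedule, config.loss)
        if not fit.converged:
            raise NumericalError("HP fit did not converge")
        artifacts["fit"] = _write_json(fit.to_dict(), out / "fit.json", chash)
        artifacts["params"] = write_params_csv(fit.params, out / "params.csv", chash)
        log_lines.append(f"fit: loss={fit.loss_value:.6g} deviance={fit.deviance} df={fit.df}")

        bootstrap = None
        if config.bootstrap_replicates:
            stage = "bootstrap"
            bootstrap = bootstrap_fit(
                schedule, config.loss,
                n_replicates=config.bootstrap_replicates, seed=config.seed,
            )
            with open(out / "bootstrap.csv", "w", encoding="utf-8") as handle:
                handle.write(_csv_header_comment(chash))
                bootstrap.to_frame().to_csv(handle, index=False)
            artifacts["bootstrap"] = out / "bootstrap.csv"

        stage = "propagate"
        scenario = config.scenario
        start = config.age_of_diagnosis + policy_delay(scenario)
        trajectory = propagate_cohort(
            fit.params, start, config.age_end,
            step=config.propagation_step, l0=config.l0, mode=config.mode,
        )
        artifacts["life_table"] = write_life_table(trajectory, out / "life_table.csv", chash)

        stage = "burden"
        band_edges = burden_metrics._bands_within(trajectory.ages[0], trajectory.ages[-1])
        report = burden_report(
            trajectory, scenario, config.economics,
            band_edges=band_edges, mean_age_rule=config.mean_age_rule,
        )
        artifacts["burden_json"] = _write_json(report.to_dict(), out / "burden.json", chash)
        with open(out / "burden.csv", "w", encoding="utf-8") as handle:
            handle.write(_csv_header_comment(chash))
            report.to_frame().to_csv(handle, index=False)
        artifacts["burden_csv"] = out / "burden.csv"
        log_lines.append(
            f"burden: YLL={report.yll_total:.3f} YPPLL={report.yppll_total:.3f} CPL={report.cpl_total:.2f}"
        )

        sweep: List[DelayResult] = []
        if config.delays:
            stage = "sweep"
            sweep = delay_sweep(
                fit.params, scenario, list(config.delays), config.economics,
                end_age=config.age_end, step=config.propagation_step,
                l0=config.l0, mode=config.mode, mean_age_rule=config.mean_age_rule,
            )
            rows = []
            for entry in sweep:
                if entry.error is not None:
                    rows.append({"delay_years": entry.delay, "metric": "error", "value": np.nan,
                                 "note": entry.error})
                    continue
                for metric, value in (
                    ("yll_total", entry.report.yll_total),
                    ("yppll_total", entry.report.yppll_total),
                    ("cpl_total", entry.report.cpl_total),
                ):
                    rows.append({"delay_years": entry.delay, "metric": metric, "value": value, "note": ""})
            with open(out / "sweep.csv", "w", encoding="utf-8") as handle:
                handle.write(_csv_header_comment(chash))
                pd.DataFrame(rows).to_csv(handle, index=False)
            artifacts["sweep"] = out / "sweep.csv"
    except Exception as exc:
        log_lines.append(f"INCOMPLETE: stage {stage!r} failed: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        if isinstance(exc, (ValidationError, NumericalError)):
            raise
        if isinstance(exc, ValueError):
            raise ValidationError(f"stage {stage!r}: {exc}") from exc
        raise NumericalError(f"stage {stage!r}: {exc}") from exc

    log_lines.append("status: complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    artifacts["log"] = out / "run.log"
    return PipelineResult(
        config=config,
        schedule=schedule,
        fit=fit,
        trajectory=trajectory,
        report=report,
        sweep=sweep,
        bootstrap=bootstrap,
        artifacts=artifacts,
    )
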