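"""Burden metrics: YLL, YPPLL and cost of productivity loss.

Three summary measures translate a cohort trajectory into societal burden:

* YLL (years of life lost): ``sum_x d_x * e_x`` — each death weighted by the
  remaining life expectancy at the age of death.
* YPPLL (years of potential productive life lost): deaths grouped into
  five-year age bands, each band contributing
  ``deaths_j * (retirement_age - mean_age_j)`` — productive years forgone
  before retirement under the human-capital approach.
* CPL (cost of productivity loss): ``YPPLL * GDP per capita`` — a flat
  human-capital valuation with one scalar output per person-year, no
  discounting and no age-earnings profile.

The reimbursement delay enters upstream: a delay of ``d`` years shifts the
cohort's starting age to ``age_of_diagnosis + d``, and every metric is
recomputed on the shifted trajectory (``delay_sweep``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hp_mortality import HPParameters, PolicyScenario, policy_delay
from .life_table import CohortTrajectory, attach_life_expectancy, propagate_cohort

__all__ = [
    "EconomicParams",
    "CohortBand",
    "BurdenReport",
    "DelayResult",
    "DEFAULT_BAND_EDGES",
    "compute_yll",
    "compute_yppll",
    "compute_cpl",
    "band_cohorts",
    "burden_report",
    "delay_sweep",
]

_TOL = 1e-9

#: The default five-year banding: 45-49 through 80-84 (85+ excluded).
DEFAULT_BAND_EDGES: Tuple[Tuple[int, int], ...] = tuple(
    (lower, lower + 4) for lower in range(45, 85, 5)
)


@dataclass(frozen=True)
class EconomicParams:
    """Scalar economic inputs of the human-capital costing."""

    gdp_per_capita: float = 17_347.0
    retirement_age: float = 67.0
    currency_label: str = "EUR"

    def __post_init__(self) -> None:
        if not np.isfinite(self.gdp_per_capita) or self.gdp_per_capita <= 0:
            raise ValueError("gdp_per_capita must be strictly positive")
        if not np.isfinite(self.retirement_age) or self.retirement_age <= 0:
            raise ValueError("retirement_age must be strictly positive")


@dataclass(frozen=True)
class CohortBand:
    """A five-year age band with its death total and representative age."""

    lower: int
    upper: int
    deaths: float
    mean_age: float

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValueError("band deaths must be non-negative")
        if not (self.lower - _TOL <= self.mean_age <= self.upper + 1 + _TOL):
            raise ValueError(
                f"mean_age {self.mean_age} outside band [{self.lower}, {self.upper + 1}]"
            )


@dataclass(frozen=True)
class BurdenReport:
    """YLL, YPPLL (per band and total) and CPL for one scenario."""

    yll_total: float
    yppll_by_band: Tuple[Tuple[CohortBand, float], ...]
    yppll_total: float
    cpl_total: float
    scenario: PolicyScenario
    economics: EconomicParams
    mode: str

    def to_dict(self) -> dict:
        return {
            "yll_total": self.yll_total,
            "yppll_total": self.yppll_total,
            "cpl_total": self.cpl_total,
            "mode": self.mode,
            "scenario": {
                "age_of_diagnosis": self.scenario.age_of_diagnosis,
                "delay_years": self.scenario.delay,
                "health_policy": self.scenario.health_policy,
                "effective_delay_years": self.scenario.effective_delay,
            },
            "economics": {
                "gdp_per_capita": self.economics.gdp_per_capita,
                "retirement_age": self.economics.retirement_age,
                "currency_label": self.economics.currency_label,
            },
            "yppll_by_band": [
                {
                    "band": f"{band.lower}-{band.upper}",
                    "deaths": band.deaths,
                    "mean_age": band.mean_age,
                    "yppll": value,
                }
                for band, value in self.yppll_by_band
            ],
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per band plus a totals row."""
        rows = [
            {
                "band": f"{band.lower}-{band.upper}",
                "deaths": band.deaths,
                "mean_age": band.mean_age,
                "yppll": value,
            }
            for band, value in self.yppll_by_band
        ]
        rows.append(
            {
                "band": "total",
                "deaths": float(sum(b.deaths for b, _ in self.yppll_by_band)),
                "mean_age": np.nan,
                "yppll": self.yppll_total,
            }
        )
        frame = pd.DataFrame(rows)
        frame["yll_total"] = self.yll_total
        frame["cpl_total"] = self.cpl_total
        return frame


def compute_yll(trajectory: CohortTrajectory) -> float:
    """Years of life lost: sum over the grid of d_x * e_x."""
    if trajectory.ex is None:
        raise ValueError(
            "trajectory has no e_x; call remaining_life_expectancy / attach_life_expectancy first"
        )
    return float(np.sum(trajectory.dx * trajectory.ex))


def compute_yppll(
    bands: Sequence[CohortBand],
    economics: EconomicParams,
    truncate: bool = True,
) -> Tuple[np.ndarray, float]:
    """Per-band and total years of potential productive life lost.

    Bands whose mean age is at or past retirement contribute 0 by default;
    ``truncate=False`` keeps the literal (possibly negative) arithmetic.
    """
    if len(bands) == 0:
        warnings.warn("empty band list; YPPLL is 0", stacklevel=2)
        return np.array([]), 0.0
    lost_years = np.array([economics.retirement_age - b.mean_age for b in bands])
    if truncate:
        lost_years = np.maximum(lost_years, 0.0)
    per_band = np.array([b.deaths for b in bands]) * lost_years
    return per_band, float(per_band.sum())


def compute_cpl(yppll_total: float, economics: EconomicParams) -> float:
    """Cost of productivity loss: YPPLL times GDP per capita."""
    if yppll_total < 0:
        raise ValueError("yppll_total must be non-negative")
    return float(yppll_total) * economics.gdp_per_capita


def band_cohorts(
    trajectory: CohortTrajectory,
    band_edges: Optional[Sequence[Tuple[int, int]]] = None,
    mean_age_rule: str = "death_weighted",
) -> List[CohortBand]:
    """Group trajectory deaths into age bands with a representative age.

    Deaths are summed over each band's half-open span ``[lower, upper + 1)``.
    ``mean_age_rule`` is ``death_weighted`` (mean of grid ages weighted by
    deaths; statistically faithful) or ``midpoint`` (``lower + width/2``).
    A band extending past the trajectory grid is refused.
    """
    if mean_age_rule not in ("death_weighted", "midpoint"):
        raise ValueError(f"unknown mean_age_rule {mean_age_rule!r}")
    edges = DEFAULT_BAND_EDGES if band_edges is None else list(band_edges)
    ages, dx = trajectory.ages, trajectory.dx
    bands: List[CohortBand] = []
    for lower, upper in edges:
        if lower + _TOL < ages[0] or upper + 1 > ages[-1] + _TOL:
            raise ValueError(
                f"band {lower}-{upper} extends beyond the trajectory grid "
                f"[{ages[0]}, {ages[-1]}]"
            )
        mask = (ages >= lower - _TOL) & (ages < upper + 1 - _TOL)
        deaths = float(dx[mask].sum())
        midpoint = lower + (upper + 1 - lower) / 2.0
        if mean_age_rule == "death_weighted" and deaths > 0:
            mean_age = float(np.sum(ages[mask] * dx[mask]) / deaths)
        else:
            mean_age = midpoint
        bands.append(CohortBand(lower=lower, upper=upper, deaths=deaths, mean_age=mean_age))
    return bands


def _bands_within(start: float, end: float) -> List[Tuple[int, int]]:
    """Default bands fully covered by the grid span [start, end]."""
    return [
        (lo, up) for lo, up in DEFAULT_BAND_EDGES
        if lo >= start - _TOL and up + 1 <= end + _TOL
    ]


def burden_report(
    trajectory: CohortTrajectory,
    scenario: PolicyScenario,
    economics: EconomicParams,
    band_edges: Optional[Sequence[Tuple[int, int]]] = None,
    mean_age_rule: str = "death_weighted",
    truncate: bool = True,
) -> BurdenReport:
    """Assemble YLL, YPPLL and CPL for one trajectory/scenario."""
    if trajectory.ex is None:
        trajectory = attach_life_expectancy(trajectory)
    bands = band_cohorts(trajectory, band_edges, mean_age_rule)
    per_band, yppll_total = compute_yppll(bands, economics, truncate=truncate)
    return BurdenReport(
        yll_total=compute_yll(trajectory),
        yppll_by_band=tuple(zip(bands, per_band.tolist())),
        yppll_total=yppll_total,
        cpl_total=compute_cpl(yppll_total, economics),
        scenario=scenario,
        economics=economics,
        mode=trajectory.mode,
    )


@dataclass(frozen=True)
class DelayResult:
    """One entry of a delay sweep: the report, or the error that stopped it."""

    delay: float
    report: Optional[BurdenReport] = None
    error: Optional[str] = None


def delay_sweep(
    params: HPParameters,
    base_scenario: PolicyScenario,
    delays: Sequence[float],
    economics: EconomicParams,
    end_age: float = 86.0,
    step: float = 0.25,
    l0: float = 160_000.0,
    mode: str = "replication",
    mean_age_rule: str = "death_weighted",
) -> List[DelayResult]:
    """Recompute the full burden pipeline for each delay value.

    Each delay shifts the cohort's starting age to
    ``age_of_diagnosis + effective delay`` and re-propagates from scratch so
    e_x stays consistent with the shifted start.  Bands are the default
    five-year bands that fit inside the shifted grid.  Deterministic; a
    delay whose shifted start falls outside the grid produces an error entry
    and the sweep continues.
    """
    delays = list(delays)
    if any(d < 0 for d in delays):
        raise ValueError("delays must be non-negative")
    if sorted(delays) != delays:
        raise ValueError("delays must be sorted ascending")
    results: List[DelayResult] = []
    for delay in delays:
        scenario = base_scenario.with_delay(delay)
        start = base_scenario.age_of_diagnosis + policy_delay(scenario)
        if start <= 0 or start >= end_age:
            results.append(DelayResult(delay=delay, error=f"shifted start age {start} outside (0, {end_age})"))
            continue
        try:
            trajectory = propagate_cohort(params, start, end_age, step=step, l0=l0, mode=mode)
            band_edges = _bands_within(trajectory.ages[0], trajectory.ages[-1])
            report = burden_report(
                trajectory, scenario, economics,
                band_edges=band_edges, mean_age_rule=mean_age_rule,
            )
        except ValueError as exc:
            results.append(DelayResult(delay=delay, error=str(exc)))
            continue
        results.append(DelayResult(delay=delay, report=report))
    return results
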