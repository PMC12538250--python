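"""Synthetic mortality schedules and trial-like cohorts.

The empirical schedule behind the framework's motivating application (a
cardiovascular-risk population aged 45-86, observed on a fine age grid) is
not publicly deposited, so this module generates statistical stand-ins with
the structure the analysis assumes: per grid age, deaths are drawn
``Binomial(exposure, q_true(age))`` with ``q_true`` the HP law at a known
parameter set, and observed probabilities are ``deaths / exposure``.  The
binomial choice matches the probability interpretation of q_x exactly (as
opposed to a Poisson count approximation).

Defaults mirror the study conditions: the reference HP parameters, ages
45-86, an initial cohort of 160,000, and a daily grid (about 15,000 age
points over 41 years) thinned to quarters via
:func:`hpburden.life_table.to_quarterly_grid`.

Reproducibility: every operation derives its generator as
``default_rng([seed, OP_CODE])``, with a distinct ``OP_CODE`` per public
operation, so a single pipeline seed yields independent, stable streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .burden_metrics import CohortBand, band_cohorts
from .hp_mortality import (
    HPParameters,
    PolicyScenario,
    REFERENCE_PARAMS,
    evaluate_qx,
    evaluate_terms,
    policy_delay,
)
from .life_table import CohortTrajectory, MortalitySchedule, attach_life_expectancy

__all__ = [
    "SyntheticConfig",
    "simulate_schedule",
    "simulate_trial_like",
    "perturb_params",
    "GRID_STEPS",
]

#: Grid spacing per named grid, in years.
GRID_STEPS = {"daily": 1.0 / 365.25, "quarterly": 0.25, "annual": 1.0}

# stream-splitting codes, one per operation
_OP_SCHEDULE = 1
_OP_TRIAL = 2
_OP_PERTURB = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for synthetic mortality data."""

    true_params: HPParameters = REFERENCE_PARAMS
    age_start: float = 45.0
    age_end: float = 86.0
    grid: str = "quarterly"
    exposure_per_age: float = 10_000.0
    l0: float = 160_000.0
    seed: int = 0
    noise_free: bool = False

    def __post_init__(self) -> None:
        if self.age_start >= self.age_end:
            raise ValueError("age_start must be below age_end")
        if self.age_start <= 0:
            raise ValueError("age_start must be strictly positive")
        if self.grid not in GRID_STEPS:
            raise ValueError(f"grid must be one of {sorted(GRID_STEPS)}")
        if self.exposure_per_age < 1:
            raise ValueError("exposure_per_age must be at least 1")
        if self.l0 <= 0:
            raise ValueError("l0 must be strictly positive")

    def age_grid(self) -> np.ndarray:
        """Half-open grid [age_start, age_end) at the configured spacing."""
        step = GRID_STEPS[self.grid]
        n = int(np.ceil((self.age_end - self.age_start) / step - 1e-9))
        return self.age_start + step * np.arange(n)


def _rng(seed: int, op_code: int) -> np.random.Generator:
    return np.random.default_rng([seed, op_code])


def simulate_schedule(config: SyntheticConfig) -> MortalitySchedule:
    """Draw an observed mortality schedule around the true HP curve.

    Per grid age: ``deaths ~ Binomial(exposure, q_true)``, observed
    ``q = deaths / exposure``.  With ``noise_free=True`` the observed curve
    equals the true curve exactly (the infinite-exposure limit) while
    exposures and expected deaths are still populated.
    """
    ages = config.age_grid()
    # validate on the raw (pre-clamp) sum: a clamped curve means the law is
    # outside its probability interpretation at that age
    child, hump, senescent = evaluate_terms(config.true_params, ages)
    raw = np.atleast_1d(np.asarray(child + hump + senescent, dtype=float))
    bad = np.nonzero((raw <= 0) | (raw >= 1))[0]
    if len(bad):
        raise ValueError(
            f"true q outside (0, 1) at age {ages[bad[0]]}: raw HP sum {raw[bad[0]]}"
        )
    q_true = raw
    exposures = np.full_like(ages, float(config.exposure_per_age))
    if config.noise_free:
        deaths = exposures * q_true
        q_obs = q_true
    else:
        rng = _rng(config.seed, _OP_SCHEDULE)
        deaths = rng.binomial(np.round(exposures).astype(np.int64), q_true).astype(float)
        q_obs = deaths / exposures
        observed_bad = np.nonzero((q_obs <= 0) | (q_obs >= 1))[0]
        if len(observed_bad):
            raise ValueError(
                "simulated deaths hit 0 or the full exposure at age "
                f"{ages[observed_bad[0]]}; increase exposure_per_age"
            )
    return MortalitySchedule(ages=ages, qx=q_obs, exposures=exposures, deaths=deaths)


def simulate_trial_like(
    config: SyntheticConfig,
    scenario: PolicyScenario,
    mode: str = "replication",
) -> Tuple[CohortTrajectory, pd.DataFrame]:
    """Stochastic twin of the deterministic cohort recursion.

    ``l0`` individuals enter at the delay-shifted diagnosis age; each
    survives a grid step with probability ``1 - q`` at the current age
    (annual q applied per step under ``replication``, converted via
    ``1 - (1-q)^step`` under ``actuarial``).  Aggregated deaths per step are
    binomial, so their expectation equals the deterministic
    :func:`hpburden.life_table.propagate_cohort` deaths.

    Returns the stochastic trajectory and a per-band death table.
    """
    start = scenario.age_of_diagnosis + policy_delay(scenario)
    if start <= 0 or start >= config.age_end:
        raise ValueError(f"shifted start age {start} outside (0, {config.age_end})")
    step = GRID_STEPS[config.grid]
    n_steps = int(np.floor((config.age_end - start) / step + 1e-9))
    if n_steps < 1:
        raise ValueError("window shorter than one grid step")
    ages = start + step * np.arange(n_steps + 1)
    q = np.atleast_1d(np.asarray(evaluate_qx(config.true_params, ages[:-1]), dtype=float))
    if mode == "actuarial":
        q_step = 1.0 - np.power(1.0 - q, step)
    elif mode == "replication":
        q_step = q
    else:
        raise ValueError(f"unknown propagation mode {mode!r}")

    rng = _rng(config.seed, _OP_TRIAL)
    alive = int(round(config.l0))
    lx = np.empty(n_steps + 1)
    dx = np.zeros(n_steps + 1)
    lx[0] = alive
    for i in range(n_steps):
        died = int(rng.binomial(alive, q_step[i])) if alive > 0 else 0
        dx[i] = died
        alive -= died
        lx[i + 1] = alive
    trajectory = attach_life_expectancy(
        CohortTrajectory(ages=ages, lx=lx, dx=dx, step=step, mode=mode)
    )
    band_edges = [
        (lo, up)
        for lo, up in ((l, l + 4) for l in range(int(np.ceil(start)), int(ages[-1]) - 3, 5))
        if lo >= start - 1e-9 and up + 1 <= ages[-1] + 1e-9
    ]
    bands: List[CohortBand] = band_cohorts(trajectory, band_edges) if band_edges else []
    band_table = pd.DataFrame(
        [
            {"band": f"{b.lower}-{b.upper}", "deaths": b.deaths, "mean_age": b.mean_age}
            for b in bands
        ]
    )
    return trajectory, band_table


def perturb_params(
    params: HPParameters, relative_scale: float, seed: int = 0
) -> HPParameters:
    """Multiply each parameter by ``exp(eps)``, ``eps ~ U(-scale, +scale)``.

    Positivity is preserved by construction; used to probe initialization
    robustness of the fit.
    """
    if not (0 <= relative_scale < 1):
        raise ValueError("relative_scale must be in [0, 1)")
    if relative_scale == 0:
        return params
    rng = _rng(seed, _OP_PERTURB)
    eps = rng.uniform(-relative_scale, relative_scale, size=8)
    return HPParameters.from_array(params.to_array() * np.exp(eps))
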