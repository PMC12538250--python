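"""Heligman-Pollard mortality law and the delay-shifted age construction.

The Heligman-Pollard (HP) "law of mortality" expresses the annual death
probability ``q_x`` — the probability that a person alive at exact age ``x``
dies before age ``x + 1`` — as the sum of three interpretable components:

    q_x = A * (x + B)^C                          (childhood decline)
        + D * exp(-E * (ln x - ln F)^2)          (accident hump)
        + G * H^x / (1 + G * H^x)                (Gompertz-type senescence)

All eight parameters are strictly positive; ``H > 1`` in any realistic fit,
so the senescent term rises logistically with age.

Delayed access to a treatment is modelled as an age shift: a patient
diagnosed at age ``a`` who waits ``delay`` years faces the mortality of age
``a + delay``.  A binary health-policy indicator switches the delay off
(policy in force => effective delay 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "HPParameters",
    "PolicyScenario",
    "ClampWarning",
    "REFERENCE_PARAMS",
    "PARAM_NAMES",
    "DAYS_PER_YEAR",
    "evaluate_qx",
    "evaluate_terms",
    "policy_delay",
    "shifted_qx",
]

PARAM_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Average calendar-year length used to convert day-denominated delays.
DAYS_PER_YEAR = 365.25

#: Probabilities are clamped to at most 1 - _CLAMP_EPS.
_CLAMP_EPS = 1e-12


class ClampWarning(UserWarning):
    """Raised (as a warning) when the raw HP sum exceeds 1 and is clamped."""


@dataclass(frozen=True)
class HPParameters:
    """The eight parameters of the Heligman-Pollard mortality law.

    Attributes
    ----------
    A : child-mortality level (probability scale).
    B : location offset of the infant decline, in years.
    C : rate of childhood mortality decline (dimensionless).
    D : accident-hump severity (probability scale).
    E : accident-hump concentration (dimensionless).
    F : accident-hump peak age, in years.
    G : senescent baseline level (probability scale).
    H : senescent rate of increase (dimensionless; > 1 in practice).
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"HP parameter {name} must be finite, got {value!r}")
            if value <= 0:
                raise ValueError(f"HP parameter {name} must be strictly positive, got {value!r}")

    def to_array(self) -> np.ndarray:
        """Flat 8-vector in the fixed order A..H."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "HPParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValueError(f"expected 8 values in order A..H, got shape {values.shape}")
        return cls(*values)

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping) -> "HPParameters":
        extra = set(mapping) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown HP parameter keys: {sorted(extra)}")
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})


#: Published point estimates for a cardiovascular-risk cohort fitted on ages
#: 45-86; used as the package default parameter set and optimizer start.
REFERENCE_PARAMS = HPParameters(
    A=3.2484e-04,
    B=4.0001e-03,
    C=2.1487e-01,
    D=9.9836e-04,
    E=1.0164e01,
    F=1.6450e01,
    G=2.9952e-03,
    H=1.0629e00,
)


@dataclass(frozen=True)
class PolicyScenario:
    """Age at diagnosis, reimbursement delay, and policy indicator.

    ``delay`` is stored in years.  Day-denominated delays (the natural unit
    of reimbursement timelines) are converted at construction via
    :meth:`from_days`.  ``health_policy`` is a binary indicator: 1 means a
    policy exists that eliminates the delay, 0 means no such policy.
    """

    age_of_diagnosis: float
    delay: float = 0.0
    health_policy: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_of_diagnosis) or self.age_of_diagnosis < 0:
            raise ValueError(f"age_of_diagnosis must be non-negative, got {self.age_of_diagnosis!r}")
        if not np.isfinite(self.delay) or self.delay < 0:
            raise ValueError(f"delay must be non-negative, got {self.delay!r}")
        if self.health_policy not in (0, 1):
            raise ValueError(f"health_policy must be 0 or 1, got {self.health_policy!r}")

    @classmethod
    def from_days(cls, age_of_diagnosis: float, delay_days: float, health_policy: int = 0) -> "PolicyScenario":
        """Build a scenario from a delay expressed in days."""
        return cls(age_of_diagnosis, float(delay_days) / DAYS_PER_YEAR, health_policy)

    @property
    def effective_delay(self) -> float:
        """Delay actually experienced: zero whenever the policy is in force."""
        return policy_delay(self)

    def with_delay(self, delay: float) -> "PolicyScenario":
        return replace(self, delay=delay)


def _check_ages(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("ages must be finite")
    if np.any(x <= 0):
        raise ValueError("ages must be strictly positive (the hump term takes ln x)")


def evaluate_terms(params: HPParameters, x):
    """Evaluate the three HP components at age(s) ``x``.

    Returns ``(childhood, hump, senescent)``, each with the shape of ``x``.
    Their sum is the raw (pre-clamp) HP probability.
    """
    x_arr = np.asarray(x, dtype=float)
    _check_ages(x_arr)
    childhood = params.A * np.power(x_arr + params.B, params.C)
    hump = params.D * np.exp(-params.E * (np.log(x_arr) - np.log(params.F)) ** 2)
    # G H^x / (1 + G H^x) computed as a logistic for numerical stability
    senescent = expit(np.log(params.G) + x_arr * np.log(params.H))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(childhood), float(hump), float(senescent)
    return childhood, hump, senescent


def evaluate_qx(params: HPParameters, x):
    """Annual death probability q_x under the HP law, clamped to [0, 1).

    The raw three-term sum can exceed 1 at extreme ages; values above
    ``1 - 1e-12`` are clamped there and a :class:`ClampWarning` is issued.
    Vectorizes over an age grid.
    """
    childhood, hump, senescent = evaluate_terms(params, x)
    raw = np.asarray(childhood) + np.asarray(hump) + np.asarray(senescent)
    limit = 1.0 - _CLAMP_EPS
    if np.any(raw > limit):
        warnings.warn(
            "raw Heligman-Pollard sum exceeds 1; clamping to 1 - 1e-12",
            ClampWarning,
            stacklevel=2,
        )
        raw = np.minimum(raw, limit)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(raw)
    return raw


def policy_delay(scenario: PolicyScenario) -> float:
    """Effective delay in years: the scenario's delay if no policy, else 0."""
    if scenario.health_policy == 1:
        return 0.0
    return float(scenario.delay)


def shifted_qx(params: HPParameters, scenario: PolicyScenario):
    """q at the delay-shifted age ``age_of_diagnosis + effective delay``."""
    x = scenario.age_of_diagnosis + policy_delay(scenario)
    return evaluate_qx(params, x)
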