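"""Estimation of Heligman-Pollard parameters from a mortality schedule.

The HP law is a nonlinear graduation: parameters are obtained by minimizing
one of eight predefined loss functions over the eight-dimensional positive
parameter space.  The classic HP objective — the relative squared error
``sum (1 - qhat/q)^2`` — is the default because it weights every age's
proportional misfit equally across four orders of magnitude of q.

All searches run in a log-parameterization (``log p`` for A..G, ``log(H-1)``
for H) so positivity and the ``H > 1`` constraint hold by construction, with
box bounds in the transformed space.  Smooth losses whose value is a sum of
squared residuals (including both deviances, via signed deviance residuals)
go through trust-region least squares; the absolute-error losses use
Nelder-Mead.  The returned loss never exceeds the loss at the start point.

Goodness of fit uses the binomial deviance against the saturated model,
referred to chi-square on (ages - 8) degrees of freedom; uncertainty comes
from a parametric bootstrap that redraws deaths from Binomial(exposure,
fitted q) per age and refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .hp_mortality import PARAM_NAMES, HPParameters, REFERENCE_PARAMS, evaluate_qx
from .life_table import MortalitySchedule

__all__ = [
    "LossSpec",
    "FitResult",
    "BootstrapResult",
    "DevianceResult",
    "LOSS_FUNCTIONS",
    "DEFAULT_LOSS",
    "DEFAULT_BOUNDS",
    "get_loss",
    "loss_value",
    "fit_hp",
    "deviance_gof",
    "bootstrap_fit",
]

N_PARAMS = 8

# -------------------------------------------------------------- losses

@dataclass(frozen=True)
class LossSpec:
    """One of the eight registered fitting objectives.

    ``residuals`` is set when the loss is a sum of squared smooth residuals
    (enabling least-squares optimization); ``needs_counts`` marks the
    deviance losses, which require deaths and exposures rather than only q.
    """

    name: str
    description: str
    value: Callable[..., float]
    residuals: Optional[Callable[..., np.ndarray]] = None
    #: d(residual)/d(fitted q), enabling an analytic Jacobian via the chain rule
    dr_dq: Optional[Callable[..., np.ndarray]] = None
    needs_counts: bool = False
    needs_positive_q: bool = True


def _binomial_deviance_units(deaths: np.ndarray, exposures: np.ndarray, q_fit: np.ndarray) -> np.ndarray:
    """Per-age contributions to the binomial deviance, with 0*ln(0/.) := 0."""
    expected = exposures * q_fit
    survivors_exp = exposures - expected
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(deaths > 0, deaths * np.log(deaths / expected), 0.0)
        t2 = np.where(
            exposures - deaths > 0,
            (exposures - deaths) * np.log((exposures - deaths) / survivors_exp),
            0.0,
        )
    units = 2.0 * (t1 + t2)
    # discordant degenerate fits: q=0 with observed deaths, or q=1 with survivors
    units = np.where((expected == 0) & (deaths > 0), np.inf, units)
    units = np.where((survivors_exp == 0) & (exposures - deaths > 0), np.inf, units)
    return units


def _poisson_deviance_units(deaths: np.ndarray, exposures: np.ndarray, q_fit: np.ndarray) -> np.ndarray:
    expected = exposures * q_fit
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(deaths > 0, deaths * np.log(deaths / expected), 0.0)
    units = 2.0 * (t - (deaths - expected))
    return np.where((expected == 0) & (deaths > 0), np.inf, units)


def _signed_sqrt(units: np.ndarray, deaths: np.ndarray, expected: np.ndarray) -> np.ndarray:
    return np.sign(deaths - expected) * np.sqrt(np.maximum(units, 0.0))


def _build_registry() -> Dict[str, LossSpec]:
    registry: Dict[str, LossSpec] = {}

    def register(spec: LossSpec) -> None:
        registry[spec.name] = spec

    register(LossSpec(
        name="relative_sse",
        description="sum (1 - qhat/q)^2  [classic HP relative squared error]",
        residuals=lambda q, qhat, d, n: 1.0 - qhat / q,
        dr_dq=lambda q, qhat, d, n: -1.0 / q,
        value=lambda q, qhat, d, n: float(np.sum((1.0 - qhat / q) ** 2)),
    ))
    register(LossSpec(
        name="absolute_sse",
        description="sum (q - qhat)^2",
        residuals=lambda q, qhat, d, n: q - qhat,
        dr_dq=lambda q, qhat, d, n: -np.ones_like(qhat),
        value=lambda q, qhat, d, n: float(np.sum((q - qhat) ** 2)),
        needs_positive_q=False,
    ))
    register(LossSpec(
        name="log_sse",
        description="sum (ln q - ln qhat)^2",
        residuals=lambda q, qhat, d, n: np.log(q) - np.log(qhat),
        dr_dq=lambda q, qhat, d, n: -1.0 / qhat,
        value=lambda q, qhat, d, n: float(np.sum((np.log(q) - np.log(qhat)) ** 2)),
    ))
    register(LossSpec(
        name="pearson_sse",
        description="sum (q - qhat)^2 / qhat  [Pearson-type weighting]",
        residuals=lambda q, qhat, d, n: (q - qhat) / np.sqrt(qhat),
        dr_dq=lambda q, qhat, d, n: -(q + qhat) / (2.0 * np.power(qhat, 1.5)),
        value=lambda q, qhat, d, n: float(np.sum((q - qhat) ** 2 / qhat)),
        needs_positive_q=False,
    ))
    register(LossSpec(
        name="binomial_deviance",
        description="binomial deviance of deaths against exposures",
        residuals=lambda q, qhat, d, n: _signed_sqrt(_binomial_deviance_units(d, n, qhat), d, n * qhat),
        value=lambda q, qhat, d, n: float(np.sum(_binomial_deviance_units(d, n, qhat))),
        needs_counts=True,
        needs_positive_q=False,
    ))
    register(LossSpec(
        name="poisson_deviance",
        description="Poisson deviance of deaths against expected deaths",
        residuals=lambda q, qhat, d, n: _signed_sqrt(_poisson_deviance_units(d, n, qhat), d, n * qhat),
        value=lambda q, qhat, d, n: float(np.sum(_poisson_deviance_units(d, n, qhat))),
        needs_counts=True,
        needs_positive_q=False,
    ))
    register(LossSpec(
        name="absolute_error",
        description="sum |q - qhat|",
        value=lambda q, qhat, d, n: float(np.sum(np.abs(q - qhat))),
        needs_positive_q=False,
    ))
    register(LossSpec(
        name="relative_absolute",
        description="sum |1 - qhat/q|",
        value=lambda q, qhat, d, n: float(np.sum(np.abs(1.0 - qhat / q))),
    ))
    return registry


LOSS_FUNCTIONS: Dict[str, LossSpec] = _build_registry()
DEFAULT_LOSS = "relative_sse"
assert len(LOSS_FUNCTIONS) == 8


def get_loss(name: str) -> LossSpec:
    try:
        return LOSS_FUNCTIONS[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose one of {sorted(LOSS_FUNCTIONS)}") from None


def loss_value(spec: LossSpec, observed: MortalitySchedule, params: HPParameters) -> float:
    """Evaluate the chosen objective at ``params`` against the schedule."""
    if isinstance(spec, str):
        spec = get_loss(spec)
    if spec.needs_counts and not observed.has_counts:
        raise ValueError(f"loss {spec.name!r} requires deaths and exposures on the schedule")
    if spec.needs_positive_q and np.any(observed.qx <= 0):
        raise ValueError(f"loss {spec.name!r} is invalid for observed q of 0")
    q_fit = np.atleast_1d(np.asarray(evaluate_qx(params, observed.ages), dtype=float))
    return spec.value(observed.qx, q_fit, observed.deaths, observed.exposures)


# ---------------------------------------------------- parameter transform

#: Default search box in natural parameter space: positive and wide for most
#: parameters, C capped at 200 (it can legitimately run far above 1 on a
#: senescence-dominated window) and H confined to (1, 2].
DEFAULT_BOUNDS: Dict[str, tuple] = {
    **{name: (1e-12, 1e6) for name in PARAM_NAMES},
    "C": (1e-12, 200.0),
    "H": (1.0 + 1e-12, 2.0),
}


def _to_internal(params: HPParameters) -> np.ndarray:
    values = params.to_array()
    theta = np.log(values)
    theta[7] = np.log(values[7] - 1.0)
    return theta


def _from_internal(theta: np.ndarray) -> HPParameters:
    values = np.exp(theta)
    values[7] = 1.0 + np.exp(theta[7])
    return HPParameters.from_array(values)


def _internal_bounds(bounds: Dict[str, tuple]) -> tuple:
    lo, hi = [], []
    for i, name in enumerate(PARAM_NAMES):
        a, b = bounds[name]
        if name == "H":
            lo.append(np.log(max(a - 1.0, 1e-300)))
            hi.append(np.log(b - 1.0))
        else:
            lo.append(np.log(a))
            hi.append(np.log(b))
    return np.array(lo), np.array(hi)


def _clip_into(params: HPParameters, bounds: Dict[str, tuple]) -> HPParameters:
    values = params.to_array()
    for i, name in enumerate(PARAM_NAMES):
        a, b = bounds[name]
        margin = 1e-9 * (b - a)
        values[i] = float(np.clip(values[i], a + margin, b - margin))
    return HPParameters.from_array(values)


def _senescent_start(ages: np.ndarray, qx: np.ndarray, base: HPParameters,
                     bounds: Dict[str, tuple]) -> HPParameters:
    """Data-driven start: logit(q) is linear in age when senescence dominates,
    so a least-squares line gives G = exp(intercept), H = exp(slope)."""
    logit_q = np.log(qx) - np.log1p(-qx)
    slope, intercept = np.polyfit(ages, logit_q, 1)
    values = base.to_array()
    values[6] = np.exp(intercept)
    values[7] = np.exp(slope)
    return _clip_into(HPParameters.from_array(np.maximum(values, 1e-12)), bounds)


# ---------------------------------------------------------------- fitting

@dataclass(frozen=True)
class FitResult:
    """Point estimate plus fit diagnostics on the observed grid."""

    params: HPParameters
    loss_name: str
    loss_value: float
    fitted_qx: MortalitySchedule
    converged: bool
    n_obs: int
    deviance: Optional[float] = None
    df: Optional[int] = None
    gof_pvalue: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loss_name": self.loss_name,
            "loss_value": self.loss_value,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "deviance": self.deviance,
            "df": self.df,
            "gof_pvalue": self.gof_pvalue,
        }


class DevianceResult(NamedTuple):
    deviance: float
    df: int
    pvalue: float


def deviance_gof(deaths, exposures, fitted_qx) -> DevianceResult:
    """Binomial deviance against the saturated model, chi-square reference.

    ``D = 2 sum_i [d_i ln(d_i/e_i) + (n_i - d_i) ln((n_i - d_i)/(n_i - e_i))]``
    with ``e_i = n_i * qhat_i`` and the convention ``0 * ln(0/.) = 0``;
    ``df = #ages - 8``; the p-value is the upper chi-square tail (NaN when
    df < 1).
    """
    deaths = np.asarray(deaths, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    fitted_qx = np.asarray(fitted_qx, dtype=float)
    if np.any(deaths < 0) or np.any(deaths > exposures):
        raise ValueError("deaths must satisfy 0 <= deaths <= exposures")
    units = _binomial_deviance_units(deaths, exposures, fitted_qx)
    deviance = float(np.sum(units))
    df = int(len(deaths) - N_PARAMS)
    pvalue = float(stats.chi2.sf(deviance, df)) if df >= 1 and np.isfinite(deviance) else (
        0.0 if not np.isfinite(deviance) and df >= 1 else float("nan")
    )
    return DevianceResult(deviance, df, pvalue)


def _q_from_theta(theta: np.ndarray, x: np.ndarray, with_grad: bool = False):
    """Fast clamped HP evaluation (and d q/d theta) in internal coordinates.

    Bypasses dataclass construction on the optimizer's hot path; must agree
    with :func:`hpburden.hp_mortality.evaluate_qx` (checked in the tests).
    """
    A, B, C, D, E, F, G = np.exp(theta[:7])
    H = 1.0 + np.exp(theta[7])
    xb = x + B
    with np.errstate(over="ignore", invalid="ignore"):
        childhood = A * np.power(xb, C)
        w = np.log(x) - np.log(F)
        hump = D * np.exp(-E * w * w)
        s = expit(np.log(G) + x * np.log(H))
        raw = childhood + hump + s
    limit = 1.0 - 1e-12
    clamped = raw > limit
    q = np.where(clamped, limit, raw)
    if not with_grad:
        return q
    sv = s * (1.0 - s)
    jac = np.empty((len(x), N_PARAMS))
    jac[:, 0] = childhood                       # d/d lnA
    jac[:, 1] = childhood * C * B / xb          # d/d lnB
    jac[:, 2] = childhood * C * np.log(xb)      # d/d lnC
    jac[:, 3] = hump                            # d/d lnD
    jac[:, 4] = -hump * E * w * w               # d/d lnE
    jac[:, 5] = 2.0 * E * w * hump              # d/d lnF
    jac[:, 6] = sv                              # d/d lnG
    jac[:, 7] = sv * x * (H - 1.0) / H          # d/d ln(H-1)
    jac[clamped, :] = 0.0
    return q, jac


def _fit_arrays(
    ages: np.ndarray,
    qx: np.ndarray,
    deaths: Optional[np.ndarray],
    exposures: Optional[np.ndarray],
    spec: LossSpec,
    init: HPParameters,
    bounds: Dict[str, tuple],
    max_evals: int = 100_000,
    tol: float = 1e-10,
) -> tuple:
    """Core optimizer on raw arrays; returns (params, loss, converged)."""
    theta0 = _to_internal(init)
    lo, hi = _internal_bounds(bounds)
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
    ages = np.asarray(ages, dtype=float)

    def q_of(theta: np.ndarray) -> np.ndarray:
        return _q_from_theta(theta, ages)

    def objective(theta: np.ndarray) -> float:
        value = spec.value(qx, q_of(theta), deaths, exposures)
        return value if np.isfinite(value) else 1e300

    if spec.residuals is not None:
        def residuals(theta: np.ndarray) -> np.ndarray:
            r = spec.residuals(qx, q_of(theta), deaths, exposures)
            return np.where(np.isfinite(r), r, 1e150)

        extra = {}
        if spec.dr_dq is not None:
            def jacobian(theta: np.ndarray) -> np.ndarray:
                q, jac_q = _q_from_theta(theta, ages, with_grad=True)
                return spec.dr_dq(qx, q, deaths, exposures)[:, None] * jac_q

            extra["jac"] = jacobian

        solution = optimize.least_squares(
            residuals,
            theta0,
            bounds=(lo, hi),
            method="trf",
            ftol=tol,
            xtol=tol,
            gtol=1e-8,
            max_nfev=max_evals,
            **extra,
        )
        theta_hat, converged = solution.x, bool(solution.success)
    else:
        solution = optimize.minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"fatol": tol, "xatol": 1e-10, "maxfev": min(max_evals, 40_000)},
        )
        theta_hat, converged = solution.x, bool(solution.success)

    final_loss = objective(theta_hat)
    init_loss = objective(theta0)
    if final_loss > init_loss:  # never leave the caller worse than the start
        theta_hat, final_loss = theta0, init_loss
    return _from_internal(theta_hat), float(final_loss), converged


def fit_hp(
    observed: MortalitySchedule,
    spec: LossSpec | str = DEFAULT_LOSS,
    init: Optional[HPParameters] = None,
    bounds: Optional[Dict[str, tuple]] = None,
) -> FitResult:
    """Fit the HP law to an observed schedule by loss minimization.

    ``init`` defaults to the package reference estimates (projected into the
    bounds); supply a perturbed or external start to probe the (multimodal)
    objective.  At least 9 observations are required so df >= 1.
    """
    if isinstance(spec, str):
        spec = get_loss(spec)
    if len(observed) < N_PARAMS + 1:
        raise ValueError(f"need at least {N_PARAMS + 1} observations, got {len(observed)}")
    if spec.needs_counts and not observed.has_counts:
        raise ValueError(f"loss {spec.name!r} requires deaths and exposures on the schedule")
    full_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        full_bounds.update(bounds)
    requested = init if init is not None else REFERENCE_PARAMS
    start = _clip_into(requested, full_bounds)
    starts = [start]
    projected = not np.allclose(start.to_array(), requested.to_array(), rtol=1e-6)
    if projected:
        # an out-of-bounds start was projected onto the box edge, which can
        # strand the search; add a data-driven senescent start as fallback
        starts.append(_senescent_start(observed.ages, observed.qx, start, full_bounds))

    best = None
    for candidate in starts:
        params, achieved, converged = _fit_arrays(
            observed.ages, observed.qx, observed.deaths, observed.exposures,
            spec, candidate, full_bounds,
        )
        if best is None or achieved < best[1]:
            best = (params, achieved, converged)
    params, achieved, converged = best
    q_fit = np.atleast_1d(np.asarray(evaluate_qx(params, observed.ages), dtype=float))
    fitted = MortalitySchedule(ages=observed.ages, qx=q_fit)
    deviance = df = pvalue = None
    if observed.has_counts:
        dev = deviance_gof(observed.deaths, observed.exposures, q_fit)
        deviance, df, pvalue = dev.deviance, dev.df, dev.pvalue
    else:
        df = len(observed) - N_PARAMS
    return FitResult(
        params=params,
        loss_name=spec.name,
        loss_value=achieved,
        fitted_qx=fitted,
        converged=converged,
        n_obs=len(observed),
        deviance=deviance,
        df=df,
        gof_pvalue=pvalue,
    )


# -------------------------------------------------------------- bootstrap

@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap replicate draws with percentile CIs and sign tests.

    p-values test H0: parameter = 0 through the basic (reflected) bootstrap
    interval — the smallest level at which that interval excludes 0 — since
    percentile intervals of positivity-constrained parameters cannot cross 0.
    """

    estimate: HPParameters
    replicates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    n_replicates: int
    n_failed: int
    seed: int
    scheme: str = "parametric"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(PARAM_NAMES),
                "estimate": self.estimate.to_array(),
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pvalue": self.pvalues,
            }
        )


def _basic_interval_pvalues(replicates: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    n_rep = replicates.shape[0]
    pvals = np.empty(estimate.shape)
    for j in range(len(estimate)):
        reflected = 2.0 * estimate[j]
        upper = np.mean(replicates[:, j] >= reflected)
        lower = np.mean(replicates[:, j] <= reflected)
        pvals[j] = np.clip(2.0 * min(upper, lower), 1.0 / (n_rep + 1), 1.0)
    return pvals


def bootstrap_fit(
    observed: MortalitySchedule,
    spec: LossSpec | str = DEFAULT_LOSS,
    n_replicates: int = 1000,
    seed: int = 0,
    scheme: str = "parametric",
    level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap CIs and p-values for the HP parameters.

    The default parametric scheme refits after redrawing deaths per age from
    Binomial(exposure, fitted q); ``scheme="nonparametric"`` resamples ages
    with replacement instead.  Replicates whose refit fails to converge are
    dropped and counted; more than 20% failures aborts.
    """
    if isinstance(spec, str):
        spec = get_loss(spec)
    if n_replicates < 100:
        raise ValueError("n_replicates must be at least 100")
    if scheme == "parametric" and not (observed.exposures is not None):
        raise ValueError("parametric bootstrap requires exposures on the schedule")

    base = fit_hp(observed, spec)
    q_hat = base.fitted_qx.qx
    rng = np.random.default_rng(seed)
    full_bounds = dict(DEFAULT_BOUNDS)

    draws = []
    n_failed = 0
    exposures = observed.exposures
    for _ in range(n_replicates):
        if scheme == "parametric":
            d_star = rng.binomial(np.round(exposures).astype(np.int64), q_hat).astype(float)
            q_star = d_star / exposures
            degenerate = (q_star <= 0) | (q_star >= 1)
            if spec.needs_positive_q and np.any(degenerate):
                n_failed += 1
                continue
            ages_star, deaths_star, exp_star = observed.ages, d_star, exposures
        elif scheme == "nonparametric":
            idx = np.sort(rng.integers(0, len(observed), len(observed)))
            ages_star = observed.ages[idx]
            q_star = observed.qx[idx]
            deaths_star = None if observed.deaths is None else observed.deaths[idx]
            exp_star = None if observed.exposures is None else observed.exposures[idx]
        else:
            raise ValueError(f"unknown bootstrap scheme {scheme!r}")
        try:
            # replicate refits tolerate 1e-8: solver noise at that level is far
            # below the bootstrap dispersion itself
            params_star, _, converged = _fit_arrays(
                ages_star, q_star, deaths_star, exp_star, spec, base.params, full_bounds,
                tol=1e-8,
            )
        except (ValueError, FloatingPointError):
            n_failed += 1
            continue
        if not converged:
            n_failed += 1
            continue
        draws.append(params_star.to_array())

    if n_failed > 0.2 * n_replicates:
        raise RuntimeError(f"bootstrap failed: {n_failed}/{n_replicates} replicates did not converge")
    replicates = np.array(draws)
    alpha = 1.0 - level
    ci_low = np.quantile(replicates, alpha / 2.0, axis=0)
    ci_high = np.quantile(replicates, 1.0 - alpha / 2.0, axis=0)
    pvalues = _basic_interval_pvalues(replicates, base.params.to_array())
    return BootstrapResult(
        estimate=base.params,
        replicates=replicates,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalues=pvalues,
        n_replicates=len(draws),
        n_failed=n_failed,
        seed=seed,
        scheme=scheme,
    )
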