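"""Loss functions, HP fitting, deviance GOF, and the bootstrap."""

import math

import numpy as np
import pytest

from hpburden.hp_mortality import HPParameters, REFERENCE_PARAMS
from hpburden.life_table import MortalitySchedule
from hpburden.model_fitting import (
    DEFAULT_BOUNDS,
    LOSS_FUNCTIONS,
    bootstrap_fit,
    deviance_gof,
    fit_hp,
    get_loss,
    loss_value,
)
from hpburden.synthetic_data import SyntheticConfig, perturb_params, simulate_schedule

TINY = 1e-300


def childhood_only(level):
    """Params whose curve is numerically constant at `level` on x in [1, 200]."""
    return HPParameters(A=level, B=1e-12, C=1e-12, D=TINY, E=1.0, F=1.0, G=TINY, H=1.0 + 1e-12)


def hp_oracle_qx(p, x):
    """Independent scalar HP evaluation (math.* only)."""
    gh = p.G * p.H ** x
    return (
        p.A * (x + p.B) ** p.C
        + p.D * math.exp(-p.E * (math.log(x) - math.log(p.F)) ** 2)
        + gh / (1.0 + gh)
    )


class TestLossValue:
    def test_eight_losses_registered(self):
        assert len(LOSS_FUNCTIONS) == 8

    def test_perfect_fit_gives_zero(self, ref_params, noise_free_quarterly):
        for name in ("relative_sse", "absolute_sse", "log_sse", "pearson_sse",
                     "absolute_error", "relative_absolute"):
            assert loss_value(get_loss(name), noise_free_quarterly, ref_params) == pytest.approx(
                0.0, abs=1e-20
            )

    def test_single_point_absolute_sse(self):
        observed = MortalitySchedule(ages=[1.0], qx=[0.2])
        assert loss_value(get_loss("absolute_sse"), observed, childhood_only(0.1)) == pytest.approx(
            0.01, rel=1e-9
        )

    def test_relative_sse_three_point_oracle(self, ref_params):
        # hand evaluation of the three residuals with an independent formula
        ages = np.array([50.0, 60.0, 70.0])
        q_obs = np.array([0.06, 0.10, 0.20])
        expected = sum(
            (1.0 - hp_oracle_qx(ref_params, x) / q) ** 2 for x, q in zip(ages, q_obs)
        )
        observed = MortalitySchedule(ages=ages, qx=q_obs)
        assert loss_value(get_loss("relative_sse"), observed, ref_params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_counts_losses_require_counts(self, noise_free_quarterly):
        bare = MortalitySchedule(ages=noise_free_quarterly.ages, qx=noise_free_quarterly.qx)
        with pytest.raises(ValueError, match="requires deaths and exposures"):
            loss_value(get_loss("binomial_deviance"), bare, REFERENCE_PARAMS)

    def test_all_losses_nonnegative(self, ref_params):
        sched = simulate_schedule(SyntheticConfig(grid="annual", exposure_per_age=1000, seed=4))
        for name, spec in LOSS_FUNCTIONS.items():
            assert loss_value(spec, sched, ref_params) >= 0.0, name


class TestFitHP:
    def test_noise_free_recovery(self, ref_params, noise_free_quarterly):
        init = perturb_params(ref_params, 0.1, seed=2)
        fit = fit_hp(noise_free_quarterly, "relative_sse", init=init)
        assert fit.converged
        rel_err = np.abs(fit.fitted_qx.qx / noise_free_quarterly.qx - 1.0)
        assert rel_err.max() < 1e-4
        assert fit.params.G == pytest.approx(ref_params.G, rel=0.01)
        assert fit.params.H == pytest.approx(ref_params.H, rel=0.01)

    def test_recovery_from_infeasible_start(self, ref_params, noise_free_quarterly):
        # multiplicative +/-10% jitter can push H below 1; the fit must still recover
        init = perturb_params(ref_params, 0.1, seed=3)
        assert init.H < 1.0  # this seed exercises the projection path
        fit = fit_hp(noise_free_quarterly, "relative_sse", init=init)
        rel_err = np.abs(fit.fitted_qx.qx / noise_free_quarterly.qx - 1.0)
        assert rel_err.max() < 1e-4

    def test_loss_monotone_from_arbitrary_start(self, noise_free_quarterly):
        init = HPParameters(A=1e-3, B=0.5, C=0.5, D=1e-3, E=5.0, F=20.0, G=1e-3, H=1.10)
        start_loss = loss_value(get_loss("relative_sse"), noise_free_quarterly, init)
        fit = fit_hp(noise_free_quarterly, "relative_sse", init=init)
        assert fit.loss_value <= start_loss

    def test_constant_schedule_smoke(self):
        ages = 1.0 + np.arange(9.0)
        observed = MortalitySchedule(ages=ages, qx=np.full(9, 0.5))
        fit = fit_hp(observed, "relative_sse")
        assert np.isfinite(fit.loss_value)
        assert fit.df == 1

    def test_requires_nine_points(self):
        observed = MortalitySchedule(ages=[1.0, 2.0], qx=[0.1, 0.2])
        with pytest.raises(ValueError, match="at least 9"):
            fit_hp(observed)

    def test_params_respect_bounds(self, noise_free_quarterly):
        fit = fit_hp(noise_free_quarterly, "relative_sse")
        values = fit.params.to_array()
        for name, value in zip("ABCDEFGH", values):
            lo, hi = DEFAULT_BOUNDS[name]
            assert lo <= value <= hi

    def test_nelder_mead_losses_smoke(self, noise_free_quarterly):
        for name in ("absolute_error", "relative_absolute"):
            fit = fit_hp(noise_free_quarterly, name)
            assert fit.loss_value < loss_value(
                get_loss(name), noise_free_quarterly,
                perturb_params(REFERENCE_PARAMS, 0.3, seed=9),
            )


class TestDevianceGOF:
    def test_saturated_agreement(self):
        exposures = np.full(12, 1000.0)
        q = np.linspace(0.1, 0.4, 12)
        deaths = exposures * q
        dev = deviance_gof(deaths, exposures, q)
        assert dev.deviance == pytest.approx(0.0, abs=1e-10)
        assert dev.df == 4
        assert dev.pvalue == pytest.approx(1.0)

    def test_single_age_zero_deviance(self):
        dev = deviance_gof([5.0], [10.0], [0.5])
        assert dev.deviance == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(dev.pvalue)  # df < 1: no chi-square reference

    def test_discordant_degenerate_fit_infinite(self):
        dev = deviance_gof([5.0], [10.0], [1.0])
        assert math.isinf(dev.deviance)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        n = np.full(20, 500.0)
        q = np.linspace(0.05, 0.5, 20)
        d = rng.binomial(500, q).astype(float)
        forward = deviance_gof(d, n, q)
        perm = rng.permutation(20)
        shuffled = deviance_gof(d[perm], n[perm], q[perm])
        assert forward.deviance == pytest.approx(shuffled.deviance, rel=1e-12)

    def test_calibration_small(self):
        # correctly specified binomial simulation: deviance/df should sit near 1
        ratios = []
        for i in range(20):
            sched = simulate_schedule(SyntheticConfig(exposure_per_age=1e4, seed=700 + i))
            fit = fit_hp(sched, "binomial_deviance")
            ratios.append(fit.deviance / fit.df)
        assert 0.9 < np.mean(ratios) < 1.1

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError, match="deaths"):
            deviance_gof([11.0], [10.0], [0.5])


@pytest.fixture(scope="module")
def annual_big_exposure():
    return simulate_schedule(SyntheticConfig(grid="annual", exposure_per_age=1e6, seed=21))


class TestBootstrap:

    def test_deterministic_under_seed(self, annual_big_exposure):
        a = bootstrap_fit(annual_big_exposure, "relative_sse", n_replicates=100, seed=5)
        b = bootstrap_fit(annual_big_exposure, "relative_sse", n_replicates=100, seed=5)
        assert np.array_equal(a.replicates, b.replicates)
        assert a.ci_low == pytest.approx(b.ci_low)
        assert a.pvalues == pytest.approx(b.pvalues)

    def test_cis_contain_generating_senescent_params(self, ref_params):
        sched = simulate_schedule(
            SyntheticConfig(grid="annual", exposure_per_age=1e6, noise_free=True)
        )
        boot = bootstrap_fit(sched, "relative_sse", n_replicates=100, seed=7)
        for idx, truth in ((6, ref_params.G), (7, ref_params.H)):
            assert boot.ci_low[idx] <= truth <= boot.ci_high[idx]

    def test_cis_bracket_point_estimate(self, annual_big_exposure):
        boot = bootstrap_fit(annual_big_exposure, "relative_sse", n_replicates=100, seed=3)
        est = boot.estimate.to_array()
        # senescent parameters are well identified; percentile CIs straddle them
        for idx in (6, 7):
            assert boot.ci_low[idx] <= est[idx] <= boot.ci_high[idx]

    def test_ci_width_shrinks_with_exposure(self):
        widths = {}
        for exposure in (1e4, 1e5):
            sched = simulate_schedule(
                SyntheticConfig(grid="annual", exposure_per_age=exposure, seed=31)
            )
            boot = bootstrap_fit(sched, "relative_sse", n_replicates=100, seed=31)
            widths[exposure] = np.median(
                (boot.ci_high - boot.ci_low) / np.abs(boot.estimate.to_array())
            )
        assert widths[1e5] < widths[1e4]

    def test_requires_minimum_replicates(self, annual_big_exposure):
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_fit(annual_big_exposure, n_replicates=50)

    def test_table_layout(self, annual_big_exposure):
        boot = bootstrap_fit(annual_big_exposure, "relative_sse", n_replicates=100, seed=13)
        frame = boot.to_frame()
        assert list(frame.columns) == ["parameter", "estimate", "ci_low", "ci_high", "pvalue"]
        assert list(frame["parameter"]) == list("ABCDEFGH")
        assert ((frame["pvalue"] > 0) & (frame["pvalue"] <= 1)).all()
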