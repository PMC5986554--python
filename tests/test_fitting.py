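"""Fitting: round-trip recovery, initialization, diagnostics, degenerate input."""

import numpy as np
import pytest

from amykin import (
    FitOptions,
    FractionCurve,
    KineticRates,
    NoiseSpec,
    NoSignalError,
    ReducedParams,
    ThTTimeCourse,
    ValidationError,
    expand_params,
    fibril_fraction,
    fit_fraction_curve,
    fit_intensity_curve,
    initial_guess,
    reduce_rates,
    simulate_tht,
)
from conftest import A_STUDY, HOURS


def make_fraction_curve(params, n=25, hours=48.0):
    t = np.linspace(0.0, hours * HOURS, n)
    return FractionCurve(times=t, fractions=fibril_fraction(params, t))


class TestFractionFit:
    def test_noise_free_round_trip(self):
        truth = ReducedParams(k=2e-4, rho=0.01)
        res = fit_fraction_curve(make_fraction_curve(truth), A_STUDY)
        assert res.converged and res.sigmoidal
        assert res.params.k == pytest.approx(truth.k, rel=1e-6)
        assert res.params.rho == pytest.approx(truth.rho, rel=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_self_consistency_random_truths(self, seed):
        rng = np.random.default_rng(seed)
        truth = ReducedParams(
            k=10 ** rng.uniform(-5, -3), rho=10 ** rng.uniform(-3, np.log10(0.3))
        )
        res = fit_fraction_curve(make_fraction_curve(truth, n=30), A_STUDY)
        assert res.params.k == pytest.approx(truth.k, rel=1e-6)
        assert res.params.rho == pytest.approx(truth.rho, rel=1e-6)

    def test_rates_consistent_with_params(self):
        truth = ReducedParams(k=2e-4, rho=0.05)
        res = fit_fraction_curve(make_fraction_curve(truth), A_STUDY)
        # kn/(ke*a) must equal the fitted rho identically
        assert res.rates.kn / (res.rates.ke * res.rates.a) == pytest.approx(
            res.params.rho, rel=1e-12
        )

    def test_flat_curve_is_no_signal(self, grid_48h):
        with pytest.raises(NoSignalError, match="no aggregation signal"):
            fit_fraction_curve(
                FractionCurve(times=grid_48h, fractions=np.zeros_like(grid_48h)), A_STUDY
            )

    def test_too_few_points_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            fit_fraction_curve(FractionCurve(times=t, fractions=t / 10), A_STUDY)

    def test_noisy_recovery_median_error(self, control_rates, grid_48h):
        # additive sigma=0.02 on the fraction scale, 100 seeded replicates
        truth = reduce_rates(control_rates)
        clean = fibril_fraction(truth, grid_48h)
        errs_kn, errs_ke = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = np.clip(clean + rng.normal(0, 0.02, grid_48h.shape), 0, 1)
            res = fit_fraction_curve(
                FractionCurve(times=grid_48h, fractions=f), A_STUDY, FitOptions(restarts=2)
            )
            errs_kn.append(abs(res.rates.kn - control_rates.kn) / control_rates.kn)
            errs_ke.append(abs(res.rates.ke - control_rates.ke) / control_rates.ke)
        assert np.median(errs_kn) <= 0.15
        assert np.median(errs_ke) <= 0.15


class TestIntensityFit:
    def test_noise_free_four_parameter_round_trip(self, grid_48h):
        truth = ReducedParams(k=2e-4, rho=0.01)
        y = 50.0 + 400.0 * fibril_fraction(truth, grid_48h)
        res = fit_intensity_curve(ThTTimeCourse(times=grid_48h, intensities=y), A_STUDY)
        assert res.F0 == pytest.approx(50.0, abs=1e-4 * 400)
        assert res.dF == pytest.approx(400.0, rel=1e-4)
        assert res.params.k == pytest.approx(truth.k, rel=1e-4)
        assert res.params.rho == pytest.approx(truth.rho, rel=1e-4)

    def test_reduces_to_fraction_fit_on_unit_scale(self, grid_48h):
        truth = ReducedParams(k=1.5e-4, rho=0.03)
        f = fibril_fraction(truth, grid_48h)
        r_frac = fit_fraction_curve(FractionCurve(times=grid_48h, fractions=f), A_STUDY)
        r_int = fit_intensity_curve(ThTTimeCourse(times=grid_48h, intensities=f), A_STUDY)
        assert r_int.params.k == pytest.approx(r_frac.params.k, rel=1e-6)
        assert r_int.params.rho == pytest.approx(r_frac.params.rho, rel=1e-6)

    def test_se_coverage_under_noise(self, control_rates, grid_48h):
        # true k within +-2 SE in at least 80% of seeded fits
        truth = reduce_rates(control_rates)
        opts = FitOptions(restarts=2)
        covered = total = 0
        for seed in range(200):
            tc = simulate_tht(
                control_rates, grid_48h, NoiseSpec(sigma_rel=0.02, seed=seed), 1
            )[0]
            res = fit_intensity_curve(tc, A_STUDY, opts)
            if res.param_se is None:
                continue
            total += 1
            covered += abs(res.params.k - truth.k) <= 2 * res.param_se[0]
        assert total > 150
        assert covered / total >= 0.80

    def test_monotone_decreasing_flagged_non_sigmoidal(self):
        t = np.linspace(0, 48 * HOURS, 10)
        y = np.linspace(400.0, 50.0, 10)
        res = fit_intensity_curve(ThTTimeCourse(times=t, intensities=y), A_STUDY)
        assert not res.sigmoidal
        assert "dF" in res.reason or "r_squared" in res.reason

    def test_constant_trace_is_no_signal(self, grid_48h):
        with pytest.raises(NoSignalError):
            fit_intensity_curve(
                ThTTimeCourse(times=grid_48h, intensities=np.full_like(grid_48h, 7.0)), A_STUDY
            )

    def test_time_unit_equivariance(self, grid_48h):
        # rescaling t by 1/3600 with k rescaled by 3600 leaves residuals identical
        truth = ReducedParams(k=2e-4, rho=0.02)
        y = 50.0 + 400.0 * fibril_fraction(truth, grid_48h)
        res_s = fit_intensity_curve(ThTTimeCourse(times=grid_48h, intensities=y), A_STUDY)
        res_h = fit_intensity_curve(
            ThTTimeCourse(times=grid_48h / HOURS, intensities=y), A_STUDY
        )
        assert res_h.params.k == pytest.approx(res_s.params.k * HOURS, rel=1e-4)
        assert res_h.sse == pytest.approx(res_s.sse, abs=1e-8 * max(res_s.sse, 1.0))


class TestInitialGuess:
    def test_within_order_of_magnitude(self):
        truth = ReducedParams(k=1e-4, rho=0.02)
        guess = initial_guess(make_fraction_curve(truth, n=100))
        assert 0.1 <= guess.k / truth.k <= 10
        assert 0.01 <= guess.rho / truth.rho <= 100  # rho is coarser but bounded

    def test_flat_curve_cannot_initialize(self, grid_48h):
        with pytest.raises(NoSignalError, match="cannot initialize"):
            initial_guess(FractionCurve(times=grid_48h, fractions=np.zeros_like(grid_48h)))

    @pytest.mark.parametrize("seed", range(10))
    def test_guess_feeds_fit_to_convergence(self, seed):
        rng = np.random.default_rng(seed)
        truth = ReducedParams(
            k=10 ** rng.uniform(-4.5, -3), rho=10 ** rng.uniform(-3, -0.7)
        )
        res = fit_fraction_curve(
            make_fraction_curve(truth, n=25), A_STUDY, FitOptions(restarts=1)
        )
        assert res.converged
        assert res.params.k == pytest.approx(truth.k, rel=1e-5)


class TestSigmoidalityCheck:
    def test_good_fit_is_sigmoidal(self):
        res = fit_fraction_curve(make_fraction_curve(ReducedParams(k=2e-4, rho=0.01)), A_STUDY)
        assert res.sigmoidal and res.reason == ""

    def test_noise_around_constant_fails_r_squared(self, grid_48h):
        rng = np.random.default_rng(7)
        f = np.clip(0.5 + rng.normal(0, 0.05, grid_48h.shape), 0, 1)
        res = fit_fraction_curve(FractionCurve(times=grid_48h, fractions=f), A_STUDY)
        assert not res.sigmoidal
        assert "r_squared" in res.reason

    def test_reason_mentions_bound_when_parameter_pinned(self):
        from amykin.fitting import sigmoidality_check
        from amykin import FitResult

        params = ReducedParams(k=1e-12, rho=0.01)
        pinned = FitResult(
            params=params,
            rates=expand_params(params, A_STUDY),
            F0=0.0,
            dF=1.0,
            sse=0.0,
            r_squared=0.99,
            converged=True,
            sigmoidal=True,
            at_bound=True,
        )
        flagged, reason = sigmoidality_check(pinned, None)
        assert not flagged.sigmoidal
        assert "bound" in reason
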