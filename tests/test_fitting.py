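"""Initialization, Nelder-Mead refinement, exclusion and residuals."""

import math
import zlib

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import relaxmap as rm
from relaxmap.fitting import T1LookupTable, _nelder_mead

from conftest import make_pixel


def brute_force_lookup(values, times, model, settings):
    """Independent exhaustive evaluation of the two-pass grid search.

    Re-derives candidate curves (unit amplitude, ideal efficiency, max-abs
    normalized on both sides) without reusing the package's table class.
    """
    s = values / np.max(np.abs(values))

    def sae(tau):
        if tau <= 0:
            e = (times == 0).astype(float)
        else:
            e = np.exp(-times / tau)
        c = 1.0 - model.ideal_b * e
        if model.magnitude:
            c = np.abs(c)
        peak = np.max(np.abs(c))
        if peak > 0:
            c = c / peak
        return np.sum(np.abs(c - s))

    coarse = np.arange(0.0, settings.t1_grid_max + 1e-9, settings.t1_coarse_step)
    errs = [sae(tau) for tau in coarse]
    center = coarse[int(np.argmin(errs))]
    lo = max(0.0, center - settings.t1_fine_halfwidth)
    hi = min(settings.t1_grid_max, center + settings.t1_fine_halfwidth)
    fine = np.arange(lo, hi + 1e-9, settings.t1_fine_step)
    errs = [sae(tau) for tau in fine]
    return float(fine[int(np.argmin(errs))])


T1_MODELS = ["ir_se_mag", "psir", "sr_bssfp", "molli_mag", "molli_psir"]


class TestLookupInit:
    def test_grid_truth_recovered_exactly(self, settings):
        values, times, model = make_pixel("ir_se_mag", tau=1000.0, B=2.0)
        assert rm.lookup_init_t1(values, model, settings, times=times) == 1000.0

    def test_fine_grid_resolution_bound(self, settings):
        """An off-grid T1 lands within one fine step (5 ms) of the truth."""
        values, times, model = make_pixel("ir_se_mag", tau=1023.0, B=2.0)
        init = rm.lookup_init_t1(values, model, settings, times=times)
        assert abs(init - 1023.0) <= 5.0
        assert init == brute_force_lookup(values, times, model, settings)

    def test_zero_signal_errors(self, settings):
        model = rm.get_model("ir_se_mag", "3p")
        with pytest.raises(rm.NoSignalError):
            rm.lookup_init_t1(np.zeros(5), model, settings, times=np.arange(5.0))

    @pytest.mark.parametrize("model_id", T1_MODELS)
    def test_oracle_equivalence_random_pixels(self, model_id, settings):
        """lookup_init_t1 matches the independent exhaustive grid search on
        100 random noisy pixels per model."""
        model = rm.get_model(model_id, "3p")
        times = rm.default_times(model_id)
        table = T1LookupTable(times, model, settings)
        rng = np.random.default_rng(zlib.crc32(model_id.encode()) % 2**31)
        for _ in range(100):
            tau = rng.uniform(50, 3000)
            B = rng.uniform(1.6, 2.2) if model.ideal_b == 2 else rng.uniform(0.85, 1.1)
            A = rng.uniform(10, 200)
            s = rm.predict_signal(model, rm.ModelParams(A, B, tau), times)
            s = s + rng.normal(0, 0.01 * A, s.shape)
            if model.magnitude:
                s = np.abs(s)
            got = table.initial_t1(s / np.max(np.abs(s)))
            assert got == brute_force_lookup(s, times, model, settings)


class TestLoglinearInit:
    def test_exact_on_noiseless_monoexponential(self, settings):
        values, times, _ = make_pixel("se_t2", "2p", tau=80.0, B=0.0)
        t2 = rm.loglinear_init_t2(values, settings, times=times)
        assert t2 == pytest.approx(80.0, abs=1e-9)

    def test_truncation_argmin_matches_enumeration(self, settings):
        """With an additive offset the truncation candidates differ; the
        winner must be the brute-force argmin over truncation levels."""
        times = rm.default_times("se_t2")
        values = 100.0 * np.exp(-times / 80.0) + 10.0

        def candidate(k):
            tt, ss = times[:k], values[:k]
            slope, intercept = np.polyfit(tt, np.log(ss), 1, w=ss)
            t2, amp = -1.0 / slope, math.exp(intercept)
            return t2, np.abs(amp * np.exp(-times / t2) - values).sum()

        cands = [candidate(k) for k in range(len(times), 2, -1)]
        expected = min(cands, key=lambda c: c[1])[0]
        assert rm.loglinear_init_t2(values, settings, times=times) == pytest.approx(expected)

    def test_three_samples_single_candidate(self, settings):
        times = np.array([10.0, 50.0, 90.0])
        values = 50.0 * np.exp(-times / 60.0)
        assert rm.loglinear_init_t2(values, settings, times=times) == pytest.approx(60.0, abs=1e-9)

    def test_nonpositive_samples_dropped_then_failure(self, settings):
        times = np.array([10.0, 50.0, 90.0, 130.0])
        values = np.array([50.0, 20.0, -1.0, 0.0])  # only 2 positive
        with pytest.raises(rm.InitializationError):
            rm.loglinear_init_t2(values, settings, times=times)


class TestRefine:
    def test_sr_3p_recovery_vs_dense_grid(self, settings):
        """Refined T1 agrees with an independent dense grid search (0.1 ms)."""
        values, times, model = make_pixel("sr_bssfp", tau=950.0, B=1.0)
        res = rm.fit_pixel(values, model, settings, times=times)
        assert res.refined
        assert abs(res.params.tau - 950.0) < 0.5
        # independent dense 1-D profile over tau with A, B at truth
        grid = np.arange(945.0, 955.0001, 0.1)
        sse = [np.sum((100 * (1 - np.exp(-times / g)) - values) ** 2) for g in grid]
        assert abs(res.params.tau - grid[int(np.argmin(sse))]) <= 0.2

    def test_molli_look_locker_corrected(self, settings):
        values, times, model = make_pixel("molli_mag", tau=700.0, B=1.8)
        res = rm.fit_pixel(values, model, settings, times=times)
        assert res.refined
        assert res.tau_corrected == pytest.approx(560.0, abs=1.0)

    def test_molli_nonphysical_b_flagged(self, settings):
        # decay-free constant signal drives B toward <= 1 -> excluded pixel
        model = rm.get_model("molli_mag", "3p")
        times = rm.default_times("molli_mag")
        init = rm.ModelParams(A=100.0, B=0.5, tau=800.0)
        values = np.full_like(times, 100.0)
        res = rm.refine_fit(values, model, init, settings, times=times)
        if res.params.B <= 1.0:
            assert res.excluded
            assert res.tau_corrected == 0.0

    def test_already_optimal_init_is_fixed_point(self, settings):
        values, times, model = make_pixel("sr_bssfp", tau=950.0, B=1.0)
        init = rm.ModelParams(A=100.0, B=1.0, tau=950.0)
        res = rm.refine_fit(values, model, init, settings, times=times)
        assert res.refined
        assert abs(res.params.tau - 950.0) < 0.5

    def test_two_vs_three_param_agree_at_ideal_efficiency(self, settings):
        for model_id in ("ir_se_mag", "sr_bssfp", "se_t2"):
            ideal = rm.get_model(model_id, "3p").ideal_b
            tau = 90.0 if model_id == "se_t2" else 900.0
            values, times, _ = make_pixel(model_id, "3p", tau=tau, B=ideal)
            r3 = rm.fit_pixel(values, rm.get_model(model_id, "3p"), settings, times=times)
            r2 = rm.fit_pixel(values, rm.get_model(model_id, "2p"), settings, times=times)
            assert abs(r3.params.tau - r2.params.tau) < 1.0

    def test_convergence_criterion_and_monotonicity(self, settings):
        values, times, model = make_pixel("ir_se_mag", tau=1234.0, B=1.9)
        res = rm.fit_pixel(values, model, settings, times=times)
        assert res.refined
        assert res.tau_spread < settings.convergence_tol
        assert res.objective_monotone

    def test_against_scipy_simplex(self, settings):
        """Dual route: our simplex and scipy's reach the same minimum."""
        from scipy.optimize import minimize

        values, times, model = make_pixel("sr_bssfp", tau=777.0, B=0.93, sigma=1.0, seed=7)
        res = rm.fit_pixel(values, model, settings, times=times)

        def sse(x):
            return np.sum((x[0] * (1 - x[1] * np.exp(-times / x[2])) - values) ** 2)

        ref = minimize(sse, [np.max(np.abs(values)), 1.0, res.initial_tau],
                       method="Nelder-Mead",
                       options=dict(xatol=1e-8, fatol=1e-12, maxiter=20000))
        assert res.params.tau == pytest.approx(ref.x[2], abs=0.5)

    def test_noise_error_envelope(self, settings):
        """SNR-50 Gaussian noise: the median |T1 error| over 500 pixels stays
        within the fine-grid resolution bound plus three spreads."""
        model = rm.get_model("sr_bssfp", "3p")
        times = rm.default_times("sr_bssfp")
        clean = rm.predict_signal(model, rm.ModelParams(100.0, 1.0, 1000.0), times)
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(500):
            noisy = clean + rng.normal(0, 2.0, clean.shape)
            res = rm.fit_pixel(noisy, model, settings, times=times)
            assert res.refined
            errs.append(res.params.tau - 1000.0)
        errs = np.array(errs)
        bound = settings.t1_fine_step / 2 + 3 * errs.std()
        assert np.median(np.abs(errs)) < bound

    def test_nelder_mead_rejects_nonfinite_start(self):
        x, f, it, conv, mono, spread, diverged = _nelder_mead(
            lambda x: math.inf, [1.0, 1.0], [0.1, 0.1], 1, 0.1, 100
        )
        assert diverged and not conv


class TestExclusion:
    @pytest.mark.parametrize("t2,keep", [(350.0, True), (399.0, True), (400.0, False), (450.0, False)])
    def test_open_interval_rule(self, t2, keep, settings):
        model = rm.get_model("se_t2", "2p")
        res = rm.FitResult(
            params=rm.ModelParams(A=100.0, B=0.0, tau=t2),
            tau_corrected=t2, residual_pct=0.0, refined=True, excluded=False,
        )
        out = rm.apply_exclusion(res, model, settings)
        if keep:
            assert not out.excluded and out.map_value == t2
        else:
            assert out.excluded and out.map_value == 0.0

    def test_t1_passthrough(self, settings):
        model = rm.get_model("sr_bssfp", "3p")
        res = rm.FitResult(
            params=rm.ModelParams(A=100.0, B=1.0, tau=3500.0),
            tau_corrected=3500.0, residual_pct=0.0, refined=True, excluded=False,
        )
        assert rm.apply_exclusion(res, model, settings) is res

    def test_pipeline_excludes_before_refinement(self, settings):
        values, times, model = make_pixel("se_t2", "2p", tau=450.0, B=0.0)
        res = rm.fit_pixel(values, model, settings, times=times)
        assert res.excluded and not res.refined
        assert res.map_value == 0.0
        assert res.n_iterations == 0  # refinement never ran


class TestResidual:
    def test_perfect_fit_zero(self, settings):
        values, times, model = make_pixel("sr_bssfp", tau=950.0, B=1.0)
        r = rm.compute_residual(values, rm.ModelParams(100.0, 1.0, 950.0), model, times=times)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ten_percent(self):
        """S = [100, 50] vs fitted curve [90, 60]: mean(10,10)/100 = 10 %."""
        model = rm.get_model("se_t2", "2p")
        t2 = 100.0
        times = np.array([0.0, t2 * math.log(1.5)])  # predictions [90, 60]
        params = rm.ModelParams(A=90.0, B=0.0, tau=t2)
        values = np.array([100.0, 50.0])
        assert rm.compute_residual(values, params, model, times=times) == pytest.approx(10.0)

    @hsettings(max_examples=30, derandomize=True)
    @given(c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c):
        model = rm.get_model("se_t2", "2p")
        times = np.array([10.0, 40.0, 90.0, 160.0])
        values = np.array([80.0, 55.0, 30.0, 12.0])
        params = rm.ModelParams(A=85.0, B=0.0, tau=70.0)
        scaled = rm.ModelParams(A=85.0 * c, B=0.0, tau=70.0)
        r1 = rm.compute_residual(values, params, model, times=times)
        r2 = rm.compute_residual(c * values, scaled, model, times=times)
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_zero_signal_flagged(self):
        model = rm.get_model("se_t2", "2p")
        with pytest.raises(rm.NoSignalError):
            rm.compute_residual(np.zeros(3), rm.ModelParams(1, 0, 50), model,
                                times=np.array([1.0, 2.0, 3.0]))


class TestSettings:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            rm.FitSettings(t1_fine_step=60.0)
        with pytest.raises(ValueError):
            rm.FitSettings(convergence_tol=0.0)
        with pytest.raises(ValueError):
            rm.FitSettings(objective="huber")

    def test_digest_tracks_changes(self):
        a, b = rm.FitSettings(), rm.FitSettings(convergence_tol=0.2)
        assert a.digest() != b.digest()
        assert a.digest() == rm.FitSettings().digest()
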