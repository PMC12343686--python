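"""Normalization arithmetic, model behavior, fitting, and R_130."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from ringfrap import (
    NormalizedTrace,
    SimulationConfig,
    TwoStateFit,
    average_traces,
    compute_r130,
    correct_and_normalize,
    fit_two_state,
    simulate_condition,
    simulate_frap_trace,
    two_state_model,
)
from ringfrap.imaging import FrapExperiment

# f(130; 0.5, 0.3, 0.05, 0.005, 0.1) evaluated symbolically to 30 digits
F130_REFERENCE = 0.758371092637685759467133496454


def make_experiment(bl, ref, bg, n_prebleach=3, dt=10.0):
    n = len(bl)
    times = dt * np.arange(n) - dt * n_prebleach
    return FrapExperiment(
        "cell", times,
        {"bleach": np.asarray(bl, float), "reference": np.asarray(ref, float),
         "background": np.asarray(bg, float)},
        n_prebleach, n_prebleach,
    )


class TestTwoStateModel:
    def test_forced_zero_at_t0_when_fully_bound(self):
        for r in (0.0, 0.3, 0.9):
            assert two_state_model(0.0, 0.4, 0.6, 0.1, 0.01, r) == 0.0

    def test_asymptote_is_mobile_fraction(self):
        assert two_state_model(1e6, 0.5, 0.4, 0.1, 0.01, 0.25) == pytest.approx(
            0.75, abs=1e-9
        )

    def test_reference_value_at_130s(self):
        assert two_state_model(130.0, 0.5, 0.3, 0.05, 0.005, 0.1) == pytest.approx(
            F130_REFERENCE, rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            two_state_model([-1.0, 0.0], 0.5, 0.3, 0.05, 0.005, 0.1)

    @pytest.mark.parametrize("bad", [
        dict(c_eq1=1.2), dict(c_eq2=-0.1), dict(r=1.0), dict(koff1=0.0),
        dict(c_eq1=0.6, c_eq2=0.6),
    ])
    def test_out_of_bound_parameters_rejected(self, bad):
        params = dict(c_eq1=0.5, c_eq2=0.3, koff1=0.05, koff2=0.005, r=0.1)
        params.update(bad)
        with pytest.raises(ValueError):
            two_state_model(10.0, **params)

    @given(
        c1=st.floats(0.0, 1.0),
        split=st.floats(0.0, 1.0),
        lk1=st.floats(-4, 0),
        dk=st.floats(0, 3),
        r=st.floats(0.0, 0.98),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_recovery_is_monotone_and_bounded(self, c1, split, lk1, dk, r):
        """f is non-decreasing in t and lives in [f(0), 1 - r)."""
        c2 = (1 - c1) * split
        k1 = 10.0**lk1
        k2 = 10.0 ** (lk1 - dk)
        t = np.linspace(0, 500, 200)
        f = two_state_model(t, c1, c2, k1, k2, r)
        assert np.all(np.diff(f) >= -1e-12)
        assert f[0] >= -1e-12
        assert np.all(f <= 1 - r + 1e-12)


class TestCorrectAndNormalize:
    def test_hand_arithmetic_frame(self):
        """Pre-bleach means 1000/2000/100; a frame at 550/1900/100 maps to
        (450/1800) * (1900/900) = 0.527778."""
        bl = [1000, 1000, 1000, 300, 550]
        ref = [2000, 2000, 2000, 2000, 1900]
        bg = [100, 100, 100, 100, 100]
        tr = correct_and_normalize(make_experiment(bl, ref, bg))
        assert tr.f_norm[4] == pytest.approx(0.5277777777777778, rel=1e-12)
        assert tr.prebleach_mean == pytest.approx(1.0, abs=1e-12)

    def test_identity_correction_without_background_or_ref_decay(self):
        bl = np.array([1000.0, 1000.0, 1000.0, 200.0, 400.0, 600.0])
        ref = np.full(6, 1500.0)
        bg = np.zeros(6)
        tr = correct_and_normalize(make_experiment(bl, ref, bg))
        np.testing.assert_allclose(tr.f_norm, bl / 1000.0, rtol=1e-12)

    def test_g_zero_at_bleach_frame_and_time_reindexed(self, noiseless_config):
        exp, _ = simulate_frap_trace(noiseless_config, 0)
        tr = correct_and_normalize(exp)
        assert tr.g[0] == 0.0
        assert tr.t_s[0] == 0.0
        assert np.all(np.diff(tr.t_s) > 0)

    def test_correction_inverts_simulated_distortions(self, sum_lt_one_params):
        cfg = SimulationConfig(
            **sum_lt_one_params, noise_sd=0.0, cell_cv=0.0,
            acq_bleach_per_frame=0.002, background_level=120.0, seed=7,
        )
        exp, truth = simulate_frap_trace(cfg, 0)
        tr = correct_and_normalize(exp)
        f = two_state_model(tr.t_s, truth.c_eq1, truth.c_eq2, truth.koff1,
                            truth.koff2, truth.r)
        assert np.abs(tr.g[1:] - f[1:]).max() <= 1e-10

    @given(
        acq=st.floats(0.0, 0.01),
        bg=st.floats(0.0, 500.0),
        depth=st.floats(0.2, 1.0),
    )
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_inversion_property_over_distortions(self, acq, bg, depth):
        cfg = SimulationConfig(
            noise_sd=0.0, cell_cv=0.0, acq_bleach_per_frame=acq,
            background_level=bg, bleach_depth=depth, prebleach_level=100.0,
            seed=3,
        )
        exp, truth = simulate_frap_trace(cfg, 0)
        tr = correct_and_normalize(exp)
        f = two_state_model(tr.t_s, truth.c_eq1, truth.c_eq2, truth.koff1,
                            truth.koff2, truth.r)
        assert np.abs(tr.g[1:] - f[1:]).max() <= 1e-10

    def test_nonpositive_reference_rejected(self):
        bl = [1000, 1000, 1000, 300, 400]
        ref = [2000, 2000, 2000, 50, 2000]
        bg = [100, 100, 100, 100, 100]
        with pytest.raises(ValueError, match="reference"):
            correct_and_normalize(make_experiment(bl, ref, bg))

    def test_no_detectable_bleach_rejected(self):
        bl = [1000.0, 1000.0, 1000.0, 1100.0, 1100.0]
        ref = [2000.0] * 5
        bg = [0.0] * 5
        with pytest.raises(ValueError, match="bleach"):
            correct_and_normalize(make_experiment(bl, ref, bg))


def _trace(cell_id, t, g):
    return NormalizedTrace(cell_id, np.asarray(t, float), np.asarray(g, float),
                           np.array([]), 0.0, 1.0)


class TestAverageTraces:
    def test_single_cell_mean_is_itself_se_missing(self):
        t = np.arange(0.0, 60.0, 10.0)
        g = np.linspace(0, 0.5, 6)
        m = average_traces([_trace("a", t, g)])
        np.testing.assert_array_equal(m.g_mean, g)
        assert np.all(np.isnan(m.g_se))
        assert m.n_cells == 1

    def test_symmetric_traces_average_to_zero(self):
        t = np.arange(0.0, 60.0, 10.0)
        g = np.linspace(0, 0.5, 6)
        m = average_traces([_trace("a", t, g), _trace("b", t, -g)])
        np.testing.assert_allclose(m.g_mean, 0.0, atol=1e-15)

    def test_identical_cells_average_to_model_curve(self, noiseless_config):
        exps, truth = simulate_condition(noiseless_config)
        traces = [correct_and_normalize(e) for e in exps]
        m = average_traces(traces)
        row = truth.iloc[0]
        f = two_state_model(m.t_s, row.c_eq1, row.c_eq2, row.koff1, row.koff2,
                            row.r)
        np.testing.assert_allclose(m.g_mean[1:], f[1:], atol=1e-12)
        np.testing.assert_allclose(m.g_se, 0.0, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = _trace("a", [0, 10, 20, 30, 40, 50], np.zeros(6))
        b = _trace("b", [0, 5, 10, 15, 20, 25], np.zeros(6))
        with pytest.raises(ValueError, match="grid"):
            average_traces([a, b])


def _best_single_state_sse(t, g):
    """Independent oracle: best single-exponential recovery fit."""
    def resid(x):
        c, lk, r = x
        return (1 - r) * (1 - c * np.exp(-(10.0**lk) * t)) - g

    best = np.inf
    for c0 in (0.3, 0.6, 0.9):
        for lk0 in (-3.0, -2.0, -1.0):
            for r0 in (0.0, 0.3):
                res = optimize.least_squares(
                    resid, [c0, lk0, r0],
                    bounds=([0, -4, 0], [1, 0, 0.99]), xtol=1e-14, ftol=1e-14,
                )
                best = min(best, 2 * res.cost)
    return best


class TestFitTwoState:
    def test_noiseless_parameters_recovered(self, sum_lt_one_params):
        cfg = SimulationConfig(**sum_lt_one_params, noise_sd=0.0, cell_cv=0.0,
                               acq_bleach_per_frame=0.0, background_level=0.0,
                               seed=2)
        exps, _ = simulate_condition(cfg)
        fit = fit_two_state(average_traces([correct_and_normalize(e) for e in exps]))
        assert fit.converged
        for name in ("c_eq1", "c_eq2", "koff1", "koff2", "r"):
            est, true = getattr(fit, name), sum_lt_one_params[name]
            assert abs(est - true) / true < 1e-4, name

    def test_labels_ordered_by_rate(self, noiseless_config):
        exps, _ = simulate_condition(noiseless_config)
        fit = fit_two_state(average_traces([correct_and_normalize(e) for e in exps]))
        assert fit.koff1 >= fit.koff2 > 0
        assert 0 <= fit.c_eq1 <= 1 and 0 <= fit.c_eq2 <= 1
        assert fit.c_eq1 + fit.c_eq2 <= 1 + 1e-9

    def test_single_exponential_data_yields_nested_fit(self):
        """On one-state data the two-state fit matches (or beats) the best
        single-state fit and assigns negligible weight to the second state."""
        t = np.arange(10.0, 270.0, 10.0)
        g = (1 - 0.1) * (1 - 0.7 * np.exp(-0.02 * t))
        fit = fit_two_state((t, g))
        assert fit.sse <= _best_single_state_sse(t, g) + 1e-12
        # the second component either vanishes or duplicates the first rate
        secondary = fit.c_eq2 * (1 - fit.r)
        assert secondary <= 0.01 or abs(fit.koff1 - fit.koff2) / fit.koff1 < 1e-3

    def test_constant_zero_trace_flagged_degenerate(self):
        # a no-recovery trace drives the fit to the r / c_eq-sum bounds;
        # zero SSE is unreachable inside the koff bounds, only approached
        t = np.arange(0.0, 270.0, 10.0)
        fit = fit_two_state((t, np.zeros_like(t)))
        assert fit.sse == pytest.approx(0.0, abs=1e-5)
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6"):
            fit_two_state((np.arange(5.0) + 1, np.zeros(5)))

    def test_koff_estimates_have_no_sign_bias(self, sum_lt_one_params):
        """Under measurement noise the rate estimates scatter around the
        truth with no systematic sign (binomial sign test, alpha = 0.01)."""
        n_rep = 40
        signs = {"koff1": 0, "koff2": 0}
        for rep in range(n_rep):
            cfg = SimulationConfig(**sum_lt_one_params, noise_sd=0.02,
                                   cell_cv=0.0, seed=50_000 + rep)
            exps, _ = simulate_condition(cfg)
            fit = fit_two_state(
                average_traces([correct_and_normalize(e) for e in exps])
            )
            for name in signs:
                if getattr(fit, name) > sum_lt_one_params[name]:
                    signs[name] += 1
        # two-sided binomial(40, 0.5) critical region at alpha = 0.01
        for name, k in signs.items():
            assert 12 <= k <= 28, f"{name}: {k}/40 above truth"


class TestComputeR130:
    def test_default_grid_reads_exact_130s_frame(self, noiseless_config):
        exps, _ = simulate_condition(noiseless_config)
        traces = [correct_and_normalize(e) for e in exps]
        assert traces[0].t_s[13] == 130.0
        res = compute_r130(traces)
        assert 0 <= res.r130_empirical_pct <= 100
        assert res.n_cells == noiseless_config.n_cells

    def test_model_value_from_reference_fit(self):
        fit = TwoStateFit(0.5, 0.3, 0.05, 0.005, 0.1, sse=0.0, converged=True,
                          n_points=27)
        t = np.arange(0.0, 270.0, 10.0)
        traces = [_trace("a", t, np.zeros_like(t)), _trace("b", t, np.zeros_like(t))]
        res = compute_r130(traces, fit)
        assert res.r130_model_pct == pytest.approx(100 * F130_REFERENCE, rel=1e-12)

    def test_noiseless_empirical_matches_model(self, noiseless_config):
        exps, _ = simulate_condition(noiseless_config)
        traces = [correct_and_normalize(e) for e in exps]
        fit = fit_two_state(average_traces(traces))
        res = compute_r130(traces, fit)
        assert abs(res.r130_empirical_pct - res.r130_model_pct) < 1e-6

    def test_se_across_cells_reported(self):
        t = np.arange(0.0, 270.0, 10.0)
        traces = [_trace(c, t, np.full_like(t, v))
                  for c, v in [("a", 0.1), ("b", 0.2), ("c", 0.3)]]
        res = compute_r130(traces)
        assert res.r130_empirical_pct == pytest.approx(20.0)
        assert res.se_pct == pytest.approx(100 * np.std([0.1, 0.2, 0.3], ddof=1)
                                           / np.sqrt(3))

    def test_target_outside_window_rejected(self):
        t = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError, match="window"):
            compute_r130([_trace("a", t, np.zeros_like(t))])
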