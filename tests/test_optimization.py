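"""UCI/ECI weight functions, wRMSE, windows, and the stepwise optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from neocolumn.optimization import (
    ECI_DECAY_A,
    InputTiming,
    OptimizationConfig,
    ParameterSpec,
    eci,
    input_cdf,
    optimization_window,
    stepwise_optimize,
    uci,
    wrmse,
)

I1 = InputTiming("p1", 25.0, 2.5)
I2 = InputTiming("d1", 60.0, 5.0)
I3 = InputTiming("p2", 125.0, 7.0)
GRID = np.linspace(0.0, 170.0, 2001)


class TestCdf:
    def test_half_at_mean(self):
        assert input_cdf(I1, 25.0) == pytest.approx(0.5)

    def test_limits(self):
        assert input_cdf(I1, -1e6) == pytest.approx(0.0)
        assert input_cdf(I1, 1e6) == pytest.approx(1.0)

    def test_one_sigma_value(self):
        # mean 26.6, sigma 2.5, t = 29.1 is one sigma above the mean
        k = InputTiming("x", 26.6, 2.5)
        assert input_cdf(k, 29.1) == pytest.approx(norm.cdf(1.0), abs=1e-9)

    def test_zero_stdev_unit_step(self):
        k = InputTiming("x", 50.0, 0.0)
        assert input_cdf(k, 49.999) == 0.0
        assert input_cdf(k, 50.0) == 1.0


class TestUci:
    def test_single_input_equals_cdf(self):
        assert np.allclose(uci(0, GRID, [I1]), input_cdf(I1, GRID))

    def test_zero_before_support(self):
        early = GRID[GRID < 10.0]
        assert np.allclose(uci(0, early, [I1, I2]), 0.0, atol=1e-9)

    def test_two_input_values(self):
        a = InputTiming("a", 25.0, 2.5)
        b = InputTiming("b", 60.0, 5.0)
        # before the second input starts, UCI_1 is simply CDF_1
        assert uci(0, np.array([30.0]), [a, b])[0] == pytest.approx(
            norm.cdf(30.0, 25.0, 2.5), abs=1e-6
        )
        # well after the second input, the subtraction drives UCI to zero
        assert uci(0, np.array([100.0]), [a, b])[0] <= 1e-12
        assert uci(0, np.array([80.0]), [a, b])[0] < 1e-3


class TestEci:
    def test_last_input_equals_cdf(self):
        e = eci(2, GRID, [I1, I2, I3], T=170.0)
        assert np.allclose(e, input_cdf(I3, GRID))

    def test_eci_ge_uci_dense_grid(self):
        for k in range(3):
            e = eci(k, GRID, [I1, I2, I3], T=170.0)
            u = uci(k, GRID, [I1, I2, I3])
            assert np.all(e >= u - 1e-12)

    def test_large_a_limit_approaches_cdf(self):
        e = eci(0, GRID, [I1, I2], T=170.0, A=1e30)
        # each subtracted term is attenuated by A^(-dmu/T) -> 0
        assert np.allclose(e, input_cdf(I1, GRID), atol=1e-5)

    @given(
        mu2=st.floats(40.0, 150.0),
        sd=st.floats(0.5, 10.0),
        a=st.floats(1.05, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_eci_dominates_uci_property(self, mu2, sd, a):
        inputs = [I1, InputTiming("x", mu2, sd)]
        e = eci(0, GRID, inputs, T=170.0, A=a)
        u = uci(0, GRID, inputs)
        assert np.all(e >= u - 1e-12)

    def test_rejects_bad_constants(self):
        with pytest.raises(ValueError):
            eci(0, GRID, [I1], T=170.0, A=1.0)
        with pytest.raises(ValueError):
            eci(0, GRID, [I1], T=0.0)

    def test_default_decay_constant(self):
        assert ECI_DECAY_A == 1.6


class TestWrmse:
    def test_uniform_weights_equal_rmse(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.standard_normal(50)
            b = rng.standard_normal(50)
            plain = np.sqrt(np.mean((a - b) ** 2))
            assert wrmse(a, b, np.ones(50)) == pytest.approx(plain, rel=1e-12)

    def test_hand_computation(self):
        assert wrmse([0.0, 1.0], [1.0, 1.0], [1.0, 3.0]) == pytest.approx(0.5)

    def test_zero_weight_region_ignored(self):
        sim = np.array([0.0, 0.0, 99.0])
        data = np.array([0.0, 0.0, 0.0])
        assert wrmse(sim, data, [1.0, 1.0, 0.0]) == 0.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            wrmse([1.0], [0.0], [0.0])


class TestWindow:
    def test_inverse_cdf_start(self):
        k = InputTiming("x", 100.0, 5.0)
        t = np.linspace(0, 170, 17001)
        w = np.asarray(input_cdf(k, t))
        t0, t1 = optimization_window(t, w, threshold=0.01)
        expected = 100.0 + 5.0 * norm.ppf(0.01)
        assert t0 == pytest.approx(expected, abs=0.1)
        assert t1 == pytest.approx(170.0)

    def test_always_above_threshold_full_span(self):
        t = np.linspace(0, 100, 101)
        t0, t1 = optimization_window(t, np.ones_like(t), threshold=0.01)
        assert (t0, t1) == (0.0, 100.0)

    def test_never_above_threshold_rejected(self):
        t = np.linspace(0, 100, 101)
        with pytest.raises(ValueError):
            optimization_window(t, np.zeros_like(t), threshold=0.01)


class TestStepwise:
    def _grid(self):
        return np.linspace(0.0, 170.0, 800)

    def test_quadratic_surrogate_recovery(self):
        t = self._grid()
        target = {"mean": 30.0, "w": 0.6}

        def forward(p):
            da = p[("p1", "start_time_mean")] - target["mean"]
            db = p[("p1", "weight:x:ampa")] - target["w"]
            return 0.05 * da * np.ones_like(t) + db * np.cos(t / 15.0)

        cfg = OptimizationConfig(
            inputs=[I1],
            parameters=[
                ParameterSpec("p1", "start_time_mean", 25.0, 15.0, 45.0),
                ParameterSpec("p1", "weight:x:ampa", 0.2, 0.0, 2.0),
            ],
            sims_per_step={"p1": 80},
            final_step_sims=80,
        )
        res = stepwise_optimize(forward, t, np.zeros_like(t), cfg)
        assert res.parameters[("p1", "start_time_mean")] == pytest.approx(
            30.0, abs=1e-3
        )
        assert res.parameters[("p1", "weight:x:ampa")] == pytest.approx(
            0.6, abs=1e-3
        )
        assert res.final_rmse < 1e-3

    def test_no_free_parameters_identity(self):
        t = self._grid()
        forward = lambda p: np.zeros_like(t)
        cfg = OptimizationConfig(inputs=[I1], parameters=[])
        res = stepwise_optimize(forward, t, np.zeros_like(t), cfg)
        assert res.parameters == {}
        assert res.final_rmse == res.initial_rmse

    def test_zero_budgets_return_initial(self):
        t = self._grid()
        forward = lambda p: p[("p1", "start_time_mean")] * np.ones_like(t)
        cfg = OptimizationConfig(
            inputs=[I1],
            parameters=[ParameterSpec("p1", "start_time_mean", 25.0, 0.0, 50.0)],
            sims_per_step={"p1": 0},
            final_step_sims=0,
        )
        res = stepwise_optimize(forward, t, np.zeros_like(t), cfg)
        assert res.parameters[("p1", "start_time_mean")] == 25.0

    def test_optimizer_respects_bounds(self):
        t = self._grid()
        seen = []

        def forward(p):
            val = p[("p1", "start_time_mean")]
            seen.append(val)
            return (val - 100.0) * np.ones_like(t)  # optimum far outside box

        cfg = OptimizationConfig(
            inputs=[I1],
            parameters=[ParameterSpec("p1", "start_time_mean", 25.0, 20.0, 30.0)],
            sims_per_step={"p1": 40},
            final_step_sims=40,
        )
        res = stepwise_optimize(forward, t, np.zeros_like(t), cfg)
        assert all(20.0 - 1e-9 <= v <= 30.0 + 1e-9 for v in seen)
        assert res.parameters[("p1", "start_time_mean")] == pytest.approx(30.0, abs=1e-6)

    def test_final_rmse_never_worse_than_initial(self):
        t = self._grid()
        rng = np.random.default_rng(0)
        data = np.sin(t / 10.0)

        def forward(p):
            a = p[("p1", "start_time_mean")]
            return np.sin(t / 10.0 + (a - 25.0) / 10.0)

        cfg = OptimizationConfig(
            inputs=[I1],
            parameters=[ParameterSpec("p1", "start_time_mean", 28.0, 15.0, 35.0)],
            sims_per_step={"p1": 25},
            final_step_sims=15,
        )
        res = stepwise_optimize(forward, t, data, cfg)
        assert res.final_rmse <= res.initial_rmse + 1e-12
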