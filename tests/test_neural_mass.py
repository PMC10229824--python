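import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from dcmerp import neural_mass as nm
from dcmerp.neural_mass import (
    DEFAULT_EXC_KERNEL,
    ExtrinsicConnection,
    InputSpec,
    ModelVariant,
    SigmoidSpec,
    SimulationGrid,
    SynapticKernel,
    build_model_space,
    channel_impulse_response,
    channel_response,
    compile_variant,
    default_source,
    exogenous_input,
    kernel_value,
    sigmoid_rate,
    simulate_erp,
)


class TestSigmoid:
    def test_zero(self):
        assert sigmoid_rate(0.0) == 0.0

    def test_asymptote(self):
        assert sigmoid_rate(100.0) > 0.499
        assert sigmoid_rate(-100.0) < -0.499

    def test_printed_value(self):
        # oracle: direct evaluation of 1/(1+exp(-0.56*1)) - 1/2
        expected = 1.0 / (1.0 + np.exp(-0.56)) - 0.5
        assert sigmoid_rate(1.0, SigmoidSpec(r=0.56)) == pytest.approx(expected, abs=1e-12)
        assert sigmoid_rate(1.0) == pytest.approx(0.13645, abs=1e-5)

    @given(st.floats(-50, 50))
    def test_odd(self, v):
        assert sigmoid_rate(v) == pytest.approx(-sigmoid_rate(-v), abs=1e-12)

    @given(st.floats(-50, 50), st.floats(0.01, 50))
    def test_strictly_increasing_and_bounded(self, v, dv):
        assert sigmoid_rate(v + dv) > sigmoid_rate(v)
        assert -0.5 < sigmoid_rate(v) < 0.5


class TestKernel:
    def test_zero_at_origin(self):
        assert kernel_value(0.0, DEFAULT_EXC_KERNEL) == 0.0

    def test_negative_t_raises(self):
        with pytest.raises(ValueError):
            kernel_value(-1.0, DEFAULT_EXC_KERNEL)

    @pytest.mark.parametrize("tau", [8.0, 16.0])
    def test_peak_at_tau(self, tau):
        k = SynapticKernel(H=4.0, tau=tau)
        res = minimize_scalar(lambda t: -kernel_value(t, k), bounds=(0.1, 100),
                              method="bounded", options={"xatol": 1e-10})
        assert res.x == pytest.approx(tau, rel=1e-6)

    @pytest.mark.parametrize("A,H,tau", [(1.0, 4.0, 8.0), (0.5, 16.0, 16.0)])
    def test_integral(self, A, H, tau):
        k = SynapticKernel(H=H, tau=tau)
        integral, _ = quad(lambda t: kernel_value(t, k, A), 0, 50 * tau)
        assert integral == pytest.approx(A * H * tau, rel=1e-3)


class TestChannel:
    def test_zero_input(self):
        V = channel_response(np.zeros(100), 4.0, 8.0, 0.1)
        assert np.all(V == 0.0)

    def test_impulse_matches_kernel(self):
        dt = 0.1
        n = 2500
        V = channel_impulse_response(n, 4.0, 8.0, dt)
        K = kernel_value(np.arange(n) * dt, DEFAULT_EXC_KERNEL)
        assert np.max(np.abs(V - K)) < 0.01 * K.max()

    def test_sampled_impulse_close(self):
        # unit-area triangular pulse (first-order-hold delta)
        dt = 0.1
        n = 2500
        u = np.zeros(n)
        u[0] = 2.0 / dt
        V = channel_response(u, 4.0, 8.0, dt)
        K = kernel_value(np.arange(n) * dt, DEFAULT_EXC_KERNEL)
        assert np.max(np.abs(V - K)) < 0.02 * K.max()

    def test_superposition(self):
        rng = np.random.default_rng(0)
        u1, u2 = rng.normal(size=(2, 500))
        V = channel_response(u1 + u2, 4.0, 8.0, 0.1)
        V12 = channel_response(u1, 4.0, 8.0, 0.1) + channel_response(u2, 4.0, 8.0, 0.1)
        assert np.allclose(V, V12, atol=1e-12)

    def test_convolution_oracle(self):
        # response to an arbitrary smooth input equals discrete convolution
        # with the closed-form kernel
        dt = 0.05
        t = np.arange(0, 120, dt)
        u = np.exp(-0.5 * ((t - 20) / 5.0) ** 2)
        V = channel_response(u, 4.0, 8.0, dt)
        K = kernel_value(t, DEFAULT_EXC_KERNEL)
        conv = np.convolve(u, K)[: len(t)] * dt
        assert np.max(np.abs(V - conv)) < 0.01 * np.max(np.abs(conv))


class TestExogenousInput:
    def test_maxima_at_onsets(self):
        spec = InputSpec()
        t = np.arange(0, 200, 0.01)
        v = exogenous_input(t, spec)
        peaks = []
        for lo, hi in ((0, 25), (25, 60)):
            seg = (t >= lo) & (t < hi)
            peaks.append(t[seg][np.argmax(v[seg])])
        assert peaks[0] == pytest.approx(10.0, abs=0.05)
        assert peaks[1] == pytest.approx(40.0, abs=0.05)

    def test_gaussian_identity(self):
        spec = InputSpec(onsets=(10.0,), dispersions=(8.0,), amplitudes=(1.0,))
        peak = exogenous_input(np.array([10.0]), spec)[0]
        at_sd = exogenous_input(np.array([18.0]), spec)[0]
        assert at_sd == pytest.approx(np.exp(-0.5) * peak, rel=1e-12)

    def test_negligible_far_from_onsets(self):
        spec = InputSpec()
        peak = exogenous_input(np.array([10.0]), spec)[0]
        assert exogenous_input(np.array([200.0]), spec)[0] < 1e-6 * peak


class TestModelSpace:
    def test_five_variants_one_null(self, model_space):
        assert len(model_space) == 5
        nulls = [v for v in model_space if not v.extrinsic]
        assert len(nulls) == 1
        assert nulls[0].id == "M5"

    def test_m1_structure(self, model_space):
        m1 = model_space[0]
        back = [c for c in m1.extrinsic if c.from_source == "vlPAG"]
        fwd = [c for c in m1.extrinsic if c.from_source == "MCN"]
        assert len(back) == 1 and back[0].prior_rate == 1.0
        assert fwd[0].target_populations == ("output",) and fwd[0].prior_rate == 1.0

    def test_m2_rates(self, model_space):
        fwd = next(c for c in model_space[1].extrinsic if c.from_source == "MCN")
        assert len(fwd.target_populations) == 2
        assert fwd.prior_rate == 0.5

    def test_m3_rates(self, model_space):
        fwd = next(c for c in model_space[2].extrinsic if c.from_source == "MCN")
        assert len(fwd.target_populations) == 3
        assert fwd.prior_rate == 0.125

    def test_delays(self, model_space):
        for v in model_space:
            for s in v.sources:
                assert all(c.delay == 2.0 for c in s.intrinsic_connections)
            assert all(c.delay == 16.0 for c in v.extrinsic)

    def test_m1_to_m4_have_both_directions(self, model_space):
        for v in model_space[:4]:
            dirs = {(c.from_source, c.to_source) for c in v.extrinsic}
            assert dirs == {("vlPAG", "MCN"), ("MCN", "vlPAG")}

    def test_ii_self_toggle(self):
        with_ii = build_model_space(ii_self=True)
        src = with_ii[0].sources[0]
        self_conns = [c for c in src.intrinsic_connections
                      if c.from_pop == c.to_pop == "inh_int"]
        assert len(self_conns) == 1
        assert all(not s.ii_self for s in build_model_space()[0].sources)


class TestSimulateErp:
    def test_null_model_ignores_extrinsic(self, m5):
        cv = compile_variant(m5)
        assert not any(n.startswith("A_") for n in cv.param_names)
        with pytest.raises(KeyError):
            cv.simulate({"A_MCN_to_vlPAG": 1.0})

    def test_null_model_separability(self, m5):
        cv = compile_variant(m5)
        base = cv.simulate()
        pert = cv.simulate({"g_exc_MCN": 0.3})
        assert np.array_equal(base[1], pert[1])
        assert not np.array_equal(base[0], pert[0])

    def test_observation_gain_linearity(self, compiled_m1):
        base = compiled_m1.simulate()
        doubled = compiled_m1.simulate({"obs_MCN": np.log(2.0)})
        assert np.allclose(doubled[0], 2.0 * base[0], rtol=1e-12)
        assert np.array_equal(doubled[1], base[1])

    def test_linearization_oracle(self, compiled_m1):
        th = {"input_amp_1": np.log(1e-3), "input_amp_2": np.log(1e-3)}
        Yn = compiled_m1.simulate(th)
        Yl = compiled_m1.simulate(th, linearize=True)
        assert np.linalg.norm(Yn - Yl) < 0.01 * np.linalg.norm(Yl)

    def test_output_grid(self, m1):
        erps = simulate_erp(m1)
        assert [e.region for e in erps] == ["MCN", "vlPAG"]
        for e in erps:
            assert e.time_ms[0] == 1.0 and e.time_ms[-1] == 200.0
            assert len(e.time_ms) == 200

    def test_dt_convergence(self, m1):
        Y1 = compile_variant(m1, SimulationGrid(dt=0.1)).simulate()
        Y2 = compile_variant(m1, SimulationGrid(dt=0.05)).simulate()
        assert np.max(np.abs(Y1 - Y2)) < 0.005 * np.max(np.abs(Y1))

    def test_unknown_parameter_raises(self, compiled_m1):
        with pytest.raises(KeyError):
            compiled_m1.simulate({"bogus": 1.0})

    def test_boundedness_within_three_prior_sd(self, m1, rng):
        from dcmerp.inversion import pack_parameters

        prior = pack_parameters(m1)
        cv = compile_variant(m1)
        for _ in range(10):
            draw = rng.uniform(-3, 3, len(prior)) * np.sqrt(prior.variance)
            Y = cv.simulate(dict(zip(prior.names, draw)))
            assert np.all(np.isfinite(Y))
            assert np.abs(Y).max() < 1e4

    def test_delay_shift_moves_cross_response(self, m5):
        src = (default_source("MCN"), default_source("vlPAG"))

        def one_way(delay):
            conn = ExtrinsicConnection("MCN", "vlPAG", ("output",), 1.0,
                                       "A_MCN_to_vlPAG", delay=delay)
            v = ModelVariant("Mtest", src, (conn,))
            return nm.CompiledVariant(v).simulate()

        null = nm.CompiledVariant(ModelVariant("Mnull", src, ())).simulate()

        def onset(delay):
            diff = np.abs(one_way(delay)[1] - null[1])
            thresh = 0.01 * diff.max()
            return np.argmax(diff > thresh)  # index on the 1 kHz grid (ms)

        shift = onset(21.0) - onset(16.0)
        assert shift == pytest.approx(5.0, abs=1.0)

    def test_reproducibility(self, compiled_m1):
        a = compiled_m1.simulate({"A_MCN_to_vlPAG": 0.3})
        b = compiled_m1.simulate({"A_MCN_to_vlPAG": 0.3})
        assert np.array_equal(a, b)


class TestArchitectureValidation:
    def test_inhibitory_origin_enforced(self):
        from dcmerp.neural_mass import IntrinsicConnection, Population, SourceArchitecture

        pops = (Population("output", "output"),
                Population("exc_int", "excitatory_interneuron"),
                Population("inh_int", "inhibitory_interneuron"))
        with pytest.raises(Exception):
            SourceArchitecture("bad", pops, (
                IntrinsicConnection("exc_int", "output", "inhibitory", 0.1),))

    def test_single_output_required(self):
        from dcmerp.neural_mass import Population, SourceArchitecture

        pops = (Population("a", "output"), Population("b", "output"))
        with pytest.raises(Exception):
            SourceArchitecture("bad", pops, ())

    def test_kernel_validation(self):
        with pytest.raises(Exception):
            SynapticKernel(H=-1.0, tau=8.0)
        with pytest.raises(Exception):
            SynapticKernel(H=4.0, tau=0.0)
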