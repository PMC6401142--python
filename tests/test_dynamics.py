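import math

import numpy as np
import pytest
from scipy.optimize import brentq

from neuralwaves.connectome import SpatialNetwork
from neuralwaves.dynamics import (
    KuramotoParams,
    NeuralMassParams,
    SimConfig,
    WilsonCowanParams,
    channel_gate,
    coupling_input,
    firing_rate,
    heun_delay_scalar,
    integrate,
    kuramoto_rhs,
    neural_mass_rhs,
    strength_to_frequency,
    wilson_cowan_rhs,
)


class TestGatesAndRates:
    def test_gate_midpoint_and_saturation(self):
        assert channel_gate(0.3, 0.3, 0.1) == pytest.approx(0.5)
        assert channel_gate(100.0, 0.0, 0.1) == pytest.approx(1.0)
        assert channel_gate(-100.0, 0.0, 0.1) == pytest.approx(0.0)

    def test_gate_one_width_above_threshold(self):
        expected = 0.5 * (1 + math.tanh(1.0))
        assert channel_gate(0.15, 0.0, 0.15) == pytest.approx(expected)
        assert expected == pytest.approx(0.8808, abs=1e-4)

    def test_rate_midpoint_monotone_symmetric(self):
        x = np.linspace(-3, 3, 101)
        q = firing_rate(x, 2.0, 0.5, 0.3)
        assert firing_rate(0.5, 2.0, 0.5, 0.3) == pytest.approx(1.0)
        assert np.all(np.diff(q) >= 0)
        d = 0.7
        assert firing_rate(0.5 + d, 2.0, 0.5, 0.3) + firing_rate(
            0.5 - d, 2.0, 0.5, 0.3
        ) == pytest.approx(2.0)

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            channel_gate(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            firing_rate(0.0, 1.0, 0.0, -1.0)


class TestCoupling:
    def test_constant_rates(self, tiny_net):
        out = coupling_input(np.full(4, 0.7), tiny_net, c=0.6)
        np.testing.assert_allclose(out, 0.6 * 0.7)

    def test_two_node_hand_case(self):
        pos = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0.0, 50.0, 0]])
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net = SpatialNetwork(pos, w)
        out = coupling_input(np.array([0.2, 0.9, 0.4]), net, c=1.0)
        assert out[0] == pytest.approx(0.9)
        assert out[1] == pytest.approx(0.2)
        assert out[2] == 0.0  # zero in-strength

    def test_matches_bruteforce_loop(self, rng):
        n = 5
        pos = rng.uniform(-50, 50, (n, 3))
        pos[0, 0] = -1.0  # ensure both hemispheres
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = SpatialNetwork(pos, w)
        rates = rng.uniform(0, 1, n)
        c = 0.37
        expected = np.zeros(n)
        for j in range(n):
            expected[j] = c * sum(w[j, k] * rates[k] for k in range(n)) / w[j].sum()
        np.testing.assert_allclose(coupling_input(rates, net, c), expected)


class TestNeuralMassRHS:
    def test_leak_only_fixed_point(self):
        p = NeuralMassParams(g_Ca=0, g_Na=0, g_K=0, a_ee=0, a_ie=0, a_ne=0)
        dV, _, _ = neural_mass_rhs(p.V_L, 0.0, 0.0, 0.0, 0.0, p)
        assert dV == pytest.approx(0.0)
        dV2, _, _ = neural_mass_rhs(p.V_L + 0.2, 0.0, 0.0, 0.0, 0.0, p)
        assert dV2 == pytest.approx(-p.g_L * 0.2)

    def test_w_fixed_point_is_gate(self):
        p = NeuralMassParams()
        V = 0.12
        w_star = channel_gate(V, p.T_K, p.d_K)
        _, _, dW = neural_mass_rhs(V, 0.0, w_star, 0.0, 0.0, p)
        assert dW == pytest.approx(0.0, abs=1e-14)

    def test_single_node_sustained_aperiodic_oscillation(self):
        """Uncoupled node: bounded, non-fixed-point attractor with a
        positive largest Lyapunov exponent (chaotic node dynamics)."""
        p = NeuralMassParams()

        def rhs(s):
            return np.array(neural_mass_rhs(s[0], s[1], s[2], 0.0, 0.0, p))

        dt = 0.02

        def heun(s, steps):
            for _ in range(steps):
                d1 = rhs(s)
                d2 = rhs(s + dt * d1)
                s = s + 0.5 * dt * (d1 + d2)
            return s

        s = np.array([0.05, 0.05, 0.3])
        s = heun(s, 50000)  # 1 s transient
        # amplitude check over 200 ms
        vs = []
        for _ in range(100):
            s = heun(s, 100)
            vs.append(s[0])
        assert np.ptp(vs) > 0.1  # not a fixed point
        # Benettin largest-Lyapunov estimate over 2 s
        d0 = 1e-7
        s2 = s + np.array([d0 / np.sqrt(3)] * 3)
        acc = 0.0
        for _ in range(200):
            s = heun(s, 500)
            s2 = heun(s2, 500)
            d = np.linalg.norm(s - s2)
            acc += math.log(d / d0)
            s2 = s + (s2 - s) * (d0 / d)
        lam = acc / (200 * 10.0)
        assert lam > 0.0


class TestWilsonCowan:
    def test_sigmoid_midpoint(self):
        du, _ = wilson_cowan_rhs(0.0, 0.0, 0.0, 0.0,
                                 WilsonCowanParams(z_e=0.0))
        assert du == pytest.approx(0.5)  # -0 + f(0)

    def test_reference_parameter_set_loads(self):
        p = WilsonCowanParams()
        assert (p.a_ee, p.a_ie, p.a_ei, p.a_ii) == (10.0, 10.0, 10.0, -2.0)
        assert (p.z_e, p.z_i, p.tau_0) == (1.5, 6.0, 1.0)

    def test_uncoupled_fixed_point_root(self):
        p = WilsonCowanParams()

        def f(x):
            return 1.0 / (1.0 + np.exp(-x))

        def v_null(u):
            # solve v = f(a_ei u - a_ii v - z_i) by fixed-point iteration
            v = 0.5
            for _ in range(200):
                v = f(p.a_ei * u - p.a_ii * v - p.z_i)
            return v

        def g(u):
            return -u + f(p.a_ee * u - p.a_ie * v_null(u) - p.z_e)

        u_star = brentq(g, 1e-6, 1 - 1e-6, xtol=1e-12)
        du, dv = wilson_cowan_rhs(u_star, v_null(u_star), 0.0, 0.0, p)
        assert abs(du) < 1e-10
        assert abs(dv) < 1e-8


class TestKuramoto:
    def test_identical_oscillators_symmetry(self, tiny_net):
        omega = np.full(4, 1.0)
        d = kuramoto_rhs(np.zeros(4), tiny_net, omega, c=0.5)
        np.testing.assert_allclose(d, 1.0)

    def test_all_equal_phases_zero_coupling_term(self, tiny_net):
        omega = np.zeros(4)
        d = kuramoto_rhs(np.full(4, 1.2), tiny_net, omega, c=0.9)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    @pytest.mark.parametrize("K,locks", [(0.6, True), (0.4, False)])
    def test_two_oscillator_lock_condition(self, K, locks):
        """Two oscillators with frequency gap d_w lock iff K >= d_w / 2
        (phase difference obeys d(psi)/dt = d_w - 2 K sin(psi))."""
        d_w = 1.0
        pos = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0.0, 9e9, 0]])
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net = SpatialNetwork(pos, w)
        omega = np.array([d_w / 2, -d_w / 2, 0.0])
        theta = np.array([0.0, 0.1, 0.0])
        dt = 0.005
        psi = []
        for _ in range(40000):
            d1 = kuramoto_rhs(theta, net, omega, K)
            d2 = kuramoto_rhs(theta + dt * d1, net, omega, K)
            theta = theta + dt / 2 * (d1 + d2)
            psi.append(theta[0] - theta[1])
        drift = abs(psi[-1] - psi[len(psi) // 2])
        if locks:
            assert drift < 0.01
        else:
            assert drift > 1.0


class TestStrengthToFrequency:
    def test_endpoints(self):
        s = np.array([1.0, 3.0, 7.0])
        w = strength_to_frequency(s)
        assert w[0] == pytest.approx(0.1)  # weakest node -> max frequency
        assert w[2] == pytest.approx(0.01)  # strongest hub -> min frequency

    def test_midpoint_value(self):
        s = np.array([0.0, 1.0, 2.0])
        w = strength_to_frequency(s)
        assert w[1] == pytest.approx(0.1 - (0.1 - 0.01) / 4)
        assert w[1] == pytest.approx(0.0775)

    def test_bounds_property(self, rng):
        s = rng.uniform(2, 50, 100)
        w = strength_to_frequency(s)
        assert np.all(w >= 0.01 - 1e-12) and np.all(w <= 0.1 + 1e-12)

    def test_constant_strengths_rejected(self):
        with pytest.raises(ValueError):
            strength_to_frequency(np.ones(5))


class TestIntegrator:
    def test_heun_order_two_on_linear_system(self):
        errs = []
        dts = [0.1, 0.05, 0.025]
        for dt in dts:
            _, x = heun_delay_scalar(-1.0, 0.0, 0.0, 1.0, dt, 2.0)
            errs.append(abs(x[-1] - math.exp(-2.0)))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_delayed_linear_matches_method_of_steps(self):
        """dx/dt = -x(t-1), x(t<=0)=1 has the piecewise-polynomial solution
        x(t) = sum_k (-1)^k (t-k+1)^k / k!."""

        def exact(t):
            return sum(
                (-1) ** k * (t - k + 1) ** k / math.factorial(k)
                for k in range(int(t) + 2)
            )

        _, x = heun_delay_scalar(0.0, -1.0, 1.0, 1.0, 0.01, 5.0)
        assert abs(x[-1] - exact(5.0)) < 1e-4

    def test_determinism_bit_identical(self, tiny_net):
        cfg = SimConfig(c=0.3, tau=0.5, dt=0.05, duration=50.0,
                        transient_discard=10.0, seed=99)
        a = integrate(tiny_net, cfg)
        b = integrate(tiny_net, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_seeded_reproducibly(self, tiny_net):
        cfg = SimConfig(c=0.3, tau=0.5, dt=0.05, duration=50.0,
                        transient_discard=10.0, seed=7, sigma=0.05)
        a = integrate(tiny_net, cfg)
        b = integrate(tiny_net, cfg)
        np.testing.assert_array_equal(a.values, b.values)
        c = integrate(tiny_net, SimConfig(c=0.3, tau=0.5, dt=0.05,
                                          duration=50.0, transient_discard=10.0,
                                          seed=8, sigma=0.05))
        assert not np.array_equal(a.values, c.values)

    def test_tau_zero_matches_reference_heun(self, tiny_net):
        """tau = 0 path equals a plain numpy Heun with the network term
        evaluated at the committed state in both stages."""
        p = NeuralMassParams()
        cfg = SimConfig(c=0.4, tau=0.0, dt=0.05, duration=5.0,
                        transient_discard=1.0, seed=21)
        traj = integrate(tiny_net, cfg, params=p)

        rng = np.random.default_rng(21)
        n = 4
        V = rng.uniform(-0.2, 0.2, n)
        Z = rng.uniform(-0.2, 0.2, n)
        W = channel_gate(V, p.T_K, p.d_K)
        rng.integers(0, 2**31 - 1)  # noise seed drawn by integrate()
        Cn = tiny_net.weights / tiny_net.weights.sum(1, keepdims=True)
        rec = []
        n_steps = int(round(6.0 / 0.05))
        rec_start = int(round(1.0 / 0.05))
        rec_every = int(round(1.0 / 0.05))
        for step in range(n_steps):
            qd = firing_rate(V, p.Q_Vmax, p.V_T, p.d_V)
            drive = Cn @ qd
            d1 = neural_mass_rhs(V, Z, W, cfg.c, drive, p)
            Vp, Zp, Wp = V + 0.05 * d1[0], Z + 0.05 * d1[1], W + 0.05 * d1[2]
            d2 = neural_mass_rhs(Vp, Zp, Wp, cfg.c, drive, p)
            V = V + 0.025 * (d1[0] + d2[0])
            Z = Z + 0.025 * (d1[1] + d2[1])
            W = W + 0.025 * (d1[2] + d2[2])
            if step + 1 >= rec_start and (step + 1 - rec_start) % rec_every == 0:
                rec.append(V.copy())
        ref = np.array(rec)[: traj.values.shape[0]]
        np.testing.assert_allclose(traj.values, ref, rtol=0, atol=1e-13)

    def test_blowup_detected(self, tiny_net):
        cfg = SimConfig(c=0.0, tau=0.0, dt=0.05, duration=20.0,
                        transient_discard=0.0, seed=1, blowup_bound=0.05)
        with pytest.raises(FloatingPointError):
            integrate(tiny_net, cfg)

    def test_kuramoto_trajectory_wrapped_and_deterministic(self, tiny_net):
        cfg = SimConfig(c=0.0028, tau=0.0, dt=10.0, duration=60_000.0,
                        transient_discard=10_000.0, seed=2, model="kuramoto",
                        record_interval=1000.0)
        a = integrate(tiny_net, cfg)
        assert np.all(np.abs(a.values) <= np.pi + 1e-12)
        b = integrate(tiny_net, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_wilson_cowan_bounded_rates(self, tiny_net):
        cfg = SimConfig(c=5.0, tau=2.0, dt=0.01, duration=100.0,
                        transient_discard=50.0, seed=3, model="wilson_cowan",
                        record_interval=0.1)
        traj = integrate(tiny_net, cfg)
        assert np.all(traj.values >= 0.0) and np.all(traj.values <= 1.0)

    def test_trajectory_h5_roundtrip(self, tmp_path, tiny_net):
        cfg = SimConfig(c=0.3, tau=0.0, dt=0.05, duration=30.0,
                        transient_discard=5.0, seed=4)
        traj = integrate(tiny_net, cfg)
        path = tmp_path / "traj.h5"
        traj.save(path)
        from neuralwaves.dynamics import Trajectory

        back = Trajectory.load(path)
        np.testing.assert_array_equal(back.values, traj.values)
        np.testing.assert_array_equal(back.times, traj.times)
        assert back.model == traj.model
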