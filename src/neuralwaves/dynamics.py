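"""Delay-coupled node models on spatial networks and their integration.

Three node models are provided, all coupled through the excitatory population
with a global coupling strength ``c`` and a uniform conduction delay ``tau``:

* a conductance-based neural mass (state: pyramidal potential V, inhibitory
  potential Z, open-potassium-channel fraction W) whose single-node dynamics
  are chaotic at the default parameters;
* a Wilson–Cowan firing-rate model (excitatory u, inhibitory v);
* a Kuramoto phase model with strength-dependent natural frequencies.

Integration is fixed-step Heun (explicit trapezoidal predictor–corrector)
with a ring buffer holding the delayed excitatory activity; delayed terms are
read from the last committed (corrector) values at t - tau in both stages, so
tau is constrained to an integer multiple of dt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .connectome import SpatialNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NeuralMassParams",
    "WilsonCowanParams",
    "KuramotoParams",
    "SimConfig",
    "Trajectory",
    "channel_gate",
    "firing_rate",
    "coupling_input",
    "neural_mass_rhs",
    "wilson_cowan_rhs",
    "kuramoto_rhs",
    "strength_to_frequency",
    "heun_delay_scalar",
    "integrate",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class NeuralMassParams:
    """Conductance-based neural mass parameters.

    Values follow the standard parameterization of the chaotic conductance
    neural mass used throughout the delay-coupled whole-brain modeling
    literature, with the excitatory gain ``a_ee`` and firing-threshold
    spread ``d_V`` set so that the default node is weakly chaotic (largest
    Lyapunov exponent ~ +1e-3 / ms) while strong global coupling (c = 0.6)
    fully synchronizes a randomized network — the regime in which spatially
    embedded networks produce metastable waves.  Potentials are
    nondimensionalized; time is in ms (unit capacitance makes
    nondimensional time numerically equal to ms).
    """

    # ion channel conductances and reversal potentials
    g_Ca: float = 1.1
    g_Na: float = 6.7
    g_K: float = 2.0
    g_L: float = 0.5
    V_Ca: float = 1.0
    V_Na: float = 0.53
    V_K: float = -0.7
    V_L: float = -0.5
    # gating thresholds / widths
    T_Ca: float = -0.01
    T_Na: float = 0.3
    T_K: float = 0.0
    d_Ca: float = 0.15
    d_Na: float = 0.15
    d_K: float = 0.3
    # firing-rate sigmoids
    Q_Vmax: float = 1.0
    Q_Zmax: float = 1.0
    V_T: float = 0.0
    Z_T: float = 0.0
    d_V: float = 0.68
    d_Z: float = 0.65
    # synaptic gains and inputs
    a_ee: float = 0.8
    a_ei: float = 2.0
    a_ie: float = 2.0
    a_ne: float = 1.0
    a_ni: float = 0.4
    r_NMDA: float = 0.25
    I_0: float = 0.3
    # rate constants for Z and W
    b: float = 0.1
    phi: float = 0.7

    def __post_init__(self) -> None:
        for name in ("d_Ca", "d_Na", "d_K", "d_V", "d_Z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Q_Vmax <= 0 or self.Q_Zmax <= 0:
            raise ValueError("maximum firing rates must be > 0")
        for name in ("g_Ca", "g_Na", "g_K", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    _ORDER = (
        "g_Ca", "g_Na", "g_K", "g_L", "V_Ca", "V_Na", "V_K", "V_L",
        "T_Ca", "T_Na", "T_K", "d_Ca", "d_Na", "d_K",
        "Q_Vmax", "Q_Zmax", "V_T", "Z_T", "d_V", "d_Z",
        "a_ee", "a_ei", "a_ie", "a_ne", "a_ni", "r_NMDA", "I_0", "b", "phi",
    )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=float)


@dataclass
class WilsonCowanParams:
    """Wilson–Cowan network parameters (delayed excitatory coupling)."""

    a_ee: float = 10.0
    a_ie: float = 10.0
    a_ei: float = 10.0
    a_ii: float = -2.0
    z_e: float = 1.5
    z_i: float = 6.0
    tau_0: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_0 <= 0:
            raise ValueError("tau_0 must be > 0")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.a_ee, self.a_ie, self.a_ei, self.a_ii,
             self.z_e, self.z_i, self.tau_0], dtype=float)


@dataclass
class KuramotoParams:
    """Kuramoto model: coupling plus the strength-to-frequency map bounds.

    Natural frequencies span [b_freq, a_freq] Hz via a quadratic map of
    anatomical node strength (strongest node gets the minimum frequency).
    The default coupling 0.0028 is the value tuned in prior whole-brain
    work to match empirical functional connectivity.
    """

    c: float = 0.0028
    a_freq: float = 0.1  # maximum frequency, Hz
    b_freq: float = 0.01  # minimum frequency, Hz

    def __post_init__(self) -> None:
        if not self.a_freq > self.b_freq > 0:
            raise ValueError("need a_freq > b_freq > 0")


@dataclass
class SimConfig:
    """Simulation configuration; times in ms."""

    c: float = 0.6
    tau: float = 1.0
    dt: float = 0.01
    duration: float = 1000.0
    transient_discard: float = 2000.0
    sigma: float = 0.0
    seed: int = 0
    record_interval: float = 1.0
    model: str = "neural_mass"
    blowup_bound: float = 20.0
    init_range: tuple[float, float] = (-0.2, 0.2)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    @property
    def delay_steps(self) -> int:
        steps = int(round(self.tau / self.dt))
        if abs(steps * self.dt - self.tau) > 1e-9 * max(1.0, self.tau):
            logger.warning(
                "tau=%g is not a multiple of dt=%g; rounded to %d steps",
                self.tau, self.dt, steps)
        return steps

    @property
    def record_every(self) -> int:
        return max(1, int(round(self.record_interval / self.dt)))


@dataclass
class Trajectory:
    """Uniformly sampled time x node record of the observable state."""

    times: np.ndarray  # ms
    values: np.ndarray  # (T, N)
    model: str = "neural_mass"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values length mismatch")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("values", data=self.values,
                              chunks=True, compression="gzip")
            fh.attrs["model"] = self.model
            for k, v in self.config.items():
                fh.attrs[f"config_{k}"] = v if v is not None else "none"

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            times = fh["times"][:]
            values = fh["values"][:]
            model = fh.attrs.get("model", "neural_mass")
            config = {k[len("config_"):]: fh.attrs[k]
                      for k in fh.attrs if k.startswith("config_")}
        return cls(times, values, str(model), config)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values)
        df.insert(0, "time_ms", self.times)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Elementary pieces (pure numpy; used by tests and the reference path)
# ---------------------------------------------------------------------------

def channel_gate(V, T_ion: float, d_ion: float):
    """Voltage-dependent fraction of open channels, in (0, 1)."""
    if d_ion <= 0:
        raise ValueError("channel width must be > 0")
    return 0.5 * (1.0 + np.tanh((np.asarray(V, dtype=float) - T_ion) / d_ion))


def firing_rate(x, max_rate: float, threshold: float, width: float):
    """Sigmoidal population firing rate 0.5*max*(1 + tanh((x - thr)/width))."""
    if width <= 0 or max_rate <= 0:
        raise ValueError("width and max_rate must be > 0")
    return 0.5 * max_rate * (1.0 + np.tanh((np.asarray(x, dtype=float) - threshold) / width))


def _normalized_coupling(weights: np.ndarray) -> np.ndarray:
    """Row-normalize the weight matrix by node in-strength (zero rows -> 0)."""
    s = weights.sum(axis=1)
    zero = s == 0
    if np.any(zero):
        logger.warning("%d node(s) with zero in-strength receive no coupling",
                       int(zero.sum()))
    sn = np.where(zero, 1.0, s)
    return weights / sn[:, None]


def coupling_input(delayed_rates: np.ndarray, net: SpatialNetwork, c: float) -> np.ndarray:
    """Per-node delayed network input c * sum_k C_jk Q_k / sum_k C_jk."""
    delayed_rates = np.asarray(delayed_rates, dtype=float)
    if delayed_rates.shape[0] != net.n_nodes:
        raise ValueError("rates length does not match network size")
    return c * (_normalized_coupling(net.weights) @ delayed_rates)


def neural_mass_rhs(V, Z, W, c, network_rate, p: NeuralMassParams):
    """Derivatives (dV, dZ, dW); ``network_rate`` is Q_j^network at t - tau.

    The excitatory drive entering both the NMDA-gated calcium term and the
    sodium term is ``(1 - c) * Q_V(V) + c * network_rate``.  Inhibition
    enters the pyramidal equation as ``-a_ie * Z * Q_Z(Z)`` (the inhibitory
    population hyperpolarizes the pyramidal cells).
    """
    V = np.asarray(V, dtype=float)
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(Z)) and np.all(np.isfinite(W))):
        raise ValueError("NaN/Inf in state")
    m_Ca = channel_gate(V, p.T_Ca, p.d_Ca)
    m_Na = channel_gate(V, p.T_Na, p.d_Na)
    m_K = channel_gate(V, p.T_K, p.d_K)
    Q_V = firing_rate(V, p.Q_Vmax, p.V_T, p.d_V)
    Q_Z = firing_rate(Z, p.Q_Zmax, p.Z_T, p.d_Z)
    drive = (1.0 - c) * Q_V + c * np.asarray(network_rate, dtype=float)
    dV = (
        -(p.g_Ca + p.r_NMDA * p.a_ee * drive) * m_Ca * (V - p.V_Ca)
        - (p.g_Na * m_Na + p.a_ee * drive) * (V - p.V_Na)
        - p.g_K * W * (V - p.V_K)
        - p.g_L * (V - p.V_L)
        - p.a_ie * Z * Q_Z
        + p.a_ne * p.I_0
    )
    dZ = p.b * (p.a_ni * p.I_0 + p.a_ei * V * Q_V)
    dW = p.phi * (m_K - W)
    return dV, dZ, dW


def wilson_cowan_rhs(u, v, delayed_network_u, c, p: WilsonCowanParams):
    """Wilson–Cowan derivatives (du, dv) with delayed excitatory input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)

    def f(x):
        return 1.0 / (1.0 + np.exp(-x))

    du = -u + f(p.a_ee * u - p.a_ie * v - p.z_e + c * np.asarray(delayed_network_u))
    dv = (-v + f(p.a_ei * u - p.a_ii * v - p.z_i)) / p.tau_0
    return du, dv


def kuramoto_rhs(theta, net: SpatialNetwork, omega: np.ndarray, c: float):
    """Kuramoto derivatives dtheta/dt (rad/s); omega in rad/s, no delay."""
    theta = np.asarray(theta, dtype=float)
    sin_t = np.sin(theta)
    cos_t = np.cos(theta)
    # sum_k C_jk sin(theta_k - theta_j) expanded via angle subtraction
    coupling = cos_t * (net.weights @ sin_t) - sin_t * (net.weights @ cos_t)
    return omega + c * coupling


def strength_to_frequency(strengths: np.ndarray, a: float = 0.1, b: float = 0.01) -> np.ndarray:
    """Quadratic strength-to-frequency map, in Hz.

    omega_j = a - (a - b) * ((s_j - s_a) / (s_b - s_a))**2 with s_a = min(s),
    s_b = max(s): the weakest node oscillates at the maximum frequency ``a``
    and the strongest hub at the minimum frequency ``b``, giving a hierarchy
    of time scales across the network.
    """
    s = np.asarray(strengths, dtype=float)
    s_a, s_b = s.min(), s.max()
    if s_a == s_b:
        raise ValueError("strengths are constant; frequency map is degenerate")
    q2 = ((s - s_a) / (s_b - s_a)) ** 2
    # algebraically a - (a-b) q^2; written so the strongest node (q = 1)
    # receives exactly b in floating point
    return b + (a - b) * (1.0 - q2)


# ---------------------------------------------------------------------------
# Numba integration kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nm_step_rhs(V, Z, W, drive_net, c, pr):
    n = V.shape[0]
    dV = np.empty(n)
    dZ = np.empty(n)
    dW = np.empty(n)
    (g_Ca, g_Na, g_K, g_L, V_Ca, V_Na, V_K, V_L,
     T_Ca, T_Na, T_K, d_Ca, d_Na, d_K,
     Q_Vmax, Q_Zmax, V_T, Z_T, d_V, d_Z,
     a_ee, a_ei, a_ie, a_ne, a_ni, r_NMDA, I_0, b, phi) = (
        pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], pr[6], pr[7],
        pr[8], pr[9], pr[10], pr[11], pr[12], pr[13],
        pr[14], pr[15], pr[16], pr[17], pr[18], pr[19],
        pr[20], pr[21], pr[22], pr[23], pr[24], pr[25], pr[26], pr[27], pr[28])
    for j in range(n):
        v = V[j]
        m_Ca = 0.5 * (1.0 + np.tanh((v - T_Ca) / d_Ca))
        m_Na = 0.5 * (1.0 + np.tanh((v - T_Na) / d_Na))
        m_K = 0.5 * (1.0 + np.tanh((v - T_K) / d_K))
        Q_V = 0.5 * Q_Vmax * (1.0 + np.tanh((v - V_T) / d_V))
        Q_Z = 0.5 * Q_Zmax * (1.0 + np.tanh((Z[j] - Z_T) / d_Z))
        drive = (1.0 - c) * Q_V + c * drive_net[j]
        dV[j] = (-(g_Ca + r_NMDA * a_ee * drive) * m_Ca * (v - V_Ca)
                 - (g_Na * m_Na + a_ee * drive) * (v - V_Na)
                 - g_K * W[j] * (v - V_K)
                 - g_L * (v - V_L)
                 - a_ie * Z[j] * Q_Z
                 + a_ne * I_0)
        dZ[j] = b * (a_ni * I_0 + a_ei * v * Q_V)
        dW[j] = phi * (m_K - W[j])
    return dV, dZ, dW


@njit(cache=True)
def _nm_integrate(Cn, V, Z, W, pr, c, dt, n_steps, delay_steps,
                  sigma, a_ne, seed, rec_every, rec_start, out, blowup):
    """Heun loop for the neural mass network.

    ``Cn`` is the strength-normalized weight matrix.  The delay ring buffer
    stores committed firing rates Q_V; both Heun stages read the same
    delayed slot.  Returns the step index of numerical blow-up, or -1.
    Also returns (via out args) the recorded V trajectory.
    """
    n = V.shape[0]
    Q_Vmax, V_T, d_V = pr[14], pr[16], pr[18]
    L = delay_steps + 1
    hist = np.empty((L, n))
    q0 = np.empty(n)
    for j in range(n):
        q0[j] = 0.5 * Q_Vmax * (1.0 + np.tanh((V[j] - V_T) / d_V))
    for m in range(L):
        for j in range(n):
            hist[m, j] = q0[j]
    np.random.seed(seed)
    sqdt = np.sqrt(dt)
    rec_i = 0
    head = 0  # slot holding the rates at the current committed time
    w_flag = 0
    for step in range(n_steps):
        delayed = hist[(head - delay_steps) % L]
        drive_net = Cn @ delayed
        dV1, dZ1, dW1 = _nm_step_rhs(V, Z, W, drive_net, c, pr)
        if sigma > 0.0:
            xi = np.random.standard_normal(n) * (a_ne * sigma * sqdt)
        else:
            xi = np.zeros(n)
        Vp = V + dt * dV1 + xi
        Zp = Z + dt * dZ1
        Wp = W + dt * dW1
        # corrector stage: the delayed state at t + dt - tau is also a
        # committed history value when tau >= dt (frozen at tau = 0)
        if delay_steps > 0:
            delayed2 = hist[(head + 1 - delay_steps) % L]
            drive_net2 = Cn @ delayed2
        else:
            drive_net2 = drive_net
        dV2, dZ2, dW2 = _nm_step_rhs(Vp, Zp, Wp, drive_net2, c, pr)
        for j in range(n):
            V[j] = V[j] + 0.5 * dt * (dV1[j] + dV2[j]) + xi[j]
            Z[j] = Z[j] + 0.5 * dt * (dZ1[j] + dZ2[j])
            W[j] = W[j] + 0.5 * dt * (dW1[j] + dW2[j])
            if W[j] < 0.0 or W[j] > 1.0:
                w_flag += 1
            if np.abs(V[j]) > blowup or not np.isfinite(V[j]):
                return step, w_flag
        head = (head + 1) % L
        for j in range(n):
            hist[head, j] = 0.5 * Q_Vmax * (1.0 + np.tanh((V[j] - V_T) / d_V))
        if step + 1 >= rec_start and (step + 1 - rec_start) % rec_every == 0:
            if rec_i < out.shape[0]:
                for j in range(n):
                    out[rec_i, j] = V[j]
                rec_i += 1
    return -1, w_flag


@njit(cache=True)
def _wc_integrate(Cn, u, v, pr, c, dt, n_steps, delay_steps,
                  rec_every, rec_start, out, blowup):
    """Heun loop for the Wilson–Cowan network (delayed excitatory coupling)."""
    n = u.shape[0]
    a_ee, a_ie, a_ei, a_ii, z_e, z_i, tau_0 = (
        pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], pr[6])
    L = delay_steps + 1
    hist = np.empty((L, n))
    for m in range(L):
        for j in range(n):
            hist[m, j] = u[j]
    rec_i = 0
    head = 0
    for step in range(n_steps):
        delayed = hist[(head - delay_steps) % L]
        u_net = Cn @ delayed
        du1 = np.empty(n)
        dv1 = np.empty(n)
        for j in range(n):
            du1[j] = -u[j] + 1.0 / (1.0 + np.exp(-(a_ee * u[j] - a_ie * v[j] - z_e + c * u_net[j])))
            dv1[j] = (-v[j] + 1.0 / (1.0 + np.exp(-(a_ei * u[j] - a_ii * v[j] - z_i)))) / tau_0
        up = u + dt * du1
        vp = v + dt * dv1
        if delay_steps > 0:
            u_net2 = Cn @ hist[(head + 1 - delay_steps) % L]
        else:
            u_net2 = u_net
        du2 = np.empty(n)
        dv2 = np.empty(n)
        for j in range(n):
            du2[j] = -up[j] + 1.0 / (1.0 + np.exp(-(a_ee * up[j] - a_ie * vp[j] - z_e + c * u_net2[j])))
            dv2[j] = (-vp[j] + 1.0 / (1.0 + np.exp(-(a_ei * up[j] - a_ii * vp[j] - z_i)))) / tau_0
        for j in range(n):
            u[j] = u[j] + 0.5 * dt * (du1[j] + du2[j])
            v[j] = v[j] + 0.5 * dt * (dv1[j] + dv2[j])
            if np.abs(u[j]) > blowup or not np.isfinite(u[j]):
                return step
        head = (head + 1) % L
        for j in range(n):
            hist[head, j] = u[j]
        if step + 1 >= rec_start and (step + 1 - rec_start) % rec_every == 0:
            if rec_i < out.shape[0]:
                for j in range(n):
                    out[rec_i, j] = u[j]
                rec_i += 1
    return -1


def heun_delay_scalar(a: float, b: float, tau: float, x0: float,
                      dt: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the scalar delay equation dx/dt = a x(t) + b x(t - tau)
    with constant history x(t <= 0) = x0, using the same Heun-with-ring-
    buffer scheme as the network integrators.  Returns (times, x).

    This is the integrator's test harness: with b = 0 it is a plain Heun
    step on dx = a x (order 2); with a = 0, b < 0 it exercises the delay
    buffer against the method-of-steps series solution.
    """
    if dt <= 0 or tau < 0:
        raise ValueError("need dt > 0 and tau >= 0")
    delay_steps = int(round(tau / dt))
    L = delay_steps + 1
    n_steps = int(round(t_end / dt))
    hist = np.full(L, float(x0))
    x = float(x0)
    head = 0
    out = np.empty(n_steps + 1)
    out[0] = x
    for step in range(n_steps):
        xd1 = hist[(head - delay_steps) % L]
        d1 = a * x + b * xd1
        xp = x + dt * d1
        xd2 = hist[(head + 1 - delay_steps) % L] if delay_steps > 0 else xd1
        d2 = a * xp + b * xd2
        x = x + 0.5 * dt * (d1 + d2)
        head = (head + 1) % L
        hist[head] = x
        out[step + 1] = x
    times = np.arange(n_steps + 1) * dt
    return times, out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def integrate(net: SpatialNetwork, config: SimConfig,
              params=None) -> Trajectory:
    """Simulate the configured model on a network and return a Trajectory.

    Initial conditions are uniform random over ``config.init_range`` for the
    membrane-potential-like variables (W starts at its V-consistent fixed
    point; Kuramoto phases start uniform on (-pi, pi]), drawn from
    ``config.seed``, so with sigma = 0 the run is fully deterministic.
    The first ``transient_discard`` ms are dropped and the recorded
    observable (V, u, or theta) is downsampled to ``record_interval``.
    """
    rng = np.random.default_rng(config.seed)
    n = net.n_nodes
    delay_steps = config.delay_steps
    total_ms = config.transient_discard + config.duration
    n_steps = int(round(total_ms / config.dt))
    rec_every = config.record_every
    rec_start = int(round(config.transient_discard / config.dt))
    n_rec = (n_steps - rec_start) // rec_every
    if n_rec < 1:
        raise ValueError("duration too short to record any sample")
    out = np.empty((n_rec, n), dtype=float)
    Cn = np.ascontiguousarray(_normalized_coupling(net.weights))
    lo, hi = config.init_range

    if config.model == "neural_mass":
        p = params if params is not None else NeuralMassParams()
        pr = p.to_array()
        V = rng.uniform(lo, hi, n)
        Z = rng.uniform(lo, hi, n)
        W = channel_gate(V, p.T_K, p.d_K)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        bad_step, w_flag = _nm_integrate(
            Cn, V, Z, W, pr, config.c, config.dt, n_steps, delay_steps,
            config.sigma, p.a_ne, noise_seed, rec_every, rec_start, out,
            config.blowup_bound)
        if bad_step >= 0:
            raise FloatingPointError(
                f"numerical blow-up at step {bad_step} "
                f"(t = {bad_step * config.dt:.3f} ms): |V| > {config.blowup_bound}")
        if w_flag > 0:
            logger.warning("W left [0, 1] at %d sample(s)", int(w_flag))
    elif config.model == "wilson_cowan":
        p = params if params is not None else WilsonCowanParams()
        pr = p.to_array()
        u = rng.uniform(max(lo, 0.0), max(hi, 0.01), n)
        v = rng.uniform(max(lo, 0.0), max(hi, 0.01), n)
        bad_step = _wc_integrate(
            Cn, u, v, pr, config.c, config.dt, n_steps, delay_steps,
            rec_every, rec_start, out, config.blowup_bound)
        if bad_step >= 0:
            raise FloatingPointError(f"numerical blow-up at step {bad_step}")
    elif config.model == "kuramoto":
        p = params if params is not None else KuramotoParams()
        omega = 2.0 * np.pi * strength_to_frequency(
            net.strengths(), p.a_freq, p.b_freq)  # rad/s
        theta = rng.uniform(-np.pi, np.pi, n)
        dt_s = config.dt / 1000.0  # integrate in seconds; config times in ms
        rec_i = 0
        for step in range(n_steps):
            d1 = kuramoto_rhs(theta, net, omega, p.c)
            d2 = kuramoto_rhs(theta + dt_s * d1, net, omega, p.c)
            theta = theta + 0.5 * dt_s * (d1 + d2)
            if step + 1 >= rec_start and (step + 1 - rec_start) % rec_every == 0:
                if rec_i < n_rec:
                    out[rec_i] = np.angle(np.exp(1j * theta))
                    rec_i += 1
    else:
        raise ValueError(f"unknown model {config.model!r}")

    t0 = config.transient_discard + rec_every * config.dt
    times = t0 + np.arange(n_rec) * rec_every * config.dt
    snapshot = asdict(config)
    snapshot["init_range"] = list(snapshot["init_range"])
    return Trajectory(times, out, config.model, snapshot)
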