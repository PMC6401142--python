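"""Analytic phase fields with known ground truth for validating the
analysis pipeline without running simulations.

Phases follow the analytic-signal convention: the phase of every node
advances in time, phi = omega * t - k . x, so the phase-gradient velocity
formula v = -(|dphi/dt| / ||grad phi||^2) grad phi points along the
direction of wave propagation.  Each fixture stores its closed-form
velocity field and verifies at build time that it equals the formula
applied to the analytic derivatives of its phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasefield import PhaseField

__all__ = [
    "WaveFixture",
    "plane_wave",
    "rotating_wave",
    "radial_pattern",
    "metastable_sequence",
]


def _wrap(phi: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phi))


@dataclass
class WaveFixture:
    """Synthetic phase field plus its ground truth."""

    positions: np.ndarray  # (N, 3) mm
    phases: np.ndarray  # (T, N), wrapped radians
    times: np.ndarray  # ms
    wave_type: str
    truth: dict = field(default_factory=dict)
    # closed-form velocity (T, N, 3) or (N, 3) if static, mm/ms
    true_velocity: np.ndarray | None = None
    true_mask: np.ndarray | None = None  # nodes where truth is defined

    def to_phasefield(self) -> PhaseField:
        return PhaseField(self.phases, self.times, self.positions)


def _check_formula(true_v: np.ndarray, grad_phi: np.ndarray,
                   dphidt: np.ndarray, mask: np.ndarray,
                   rtol: float = 1e-6) -> None:
    """Assert stored truth equals -(|dphi/dt| / ||grad||^2) grad."""
    norm2 = np.einsum("...i,...i->...", grad_phi, grad_phi)
    ok = mask & (norm2 > 1e-18)
    v = np.zeros_like(grad_phi)
    v[ok] = -(np.abs(dphidt)[ok] / norm2[ok])[..., None] * grad_phi[ok]
    err = np.linalg.norm(v[ok] - true_v[ok], axis=-1)
    scale = np.linalg.norm(true_v[ok], axis=-1) + 1e-300
    if ok.any() and np.max(err / scale) > rtol:
        raise AssertionError("fixture truth velocity violates the phase "
                             "velocity formula")


def plane_wave(positions: np.ndarray, wavevector, angular_freq: float,
               duration: float = 200.0, dt: float = 1.0) -> WaveFixture:
    """Traveling plane wave: phi = omega*t - k.x; v = (omega/||k||^2) k."""
    k = np.asarray(wavevector, dtype=float)
    if np.linalg.norm(k) == 0:
        raise ValueError("wavevector must be nonzero")
    positions = np.asarray(positions, dtype=float)
    times = np.arange(0.0, duration, dt)
    phi = angular_freq * times[:, None] - positions @ k
    n = positions.shape[0]
    k2 = float(k @ k)
    v = np.broadcast_to(np.abs(angular_freq) / k2 * k, (n, 3)).copy()
    mask = np.ones(n, dtype=bool)
    grad = np.broadcast_to(-k, (n, 3))
    dphidt = np.full(n, angular_freq)
    if angular_freq != 0:
        _check_formula(v, grad, dphidt, mask)
    else:
        v = np.zeros((n, 3))
    return WaveFixture(positions, _wrap(phi), times, "plane",
                       {"wavevector": k, "angular_freq": angular_freq,
                        "speed": abs(angular_freq) / np.sqrt(k2)},
                       v, mask)


def rotating_wave(positions: np.ndarray, axis=(0.0, 0.0, 1.0),
                  center=(0.0, 0.0, 0.0), angular_freq: float = 0.5,
                  duration: float = 200.0, dt: float = 1.0,
                  core_radius: float = 1e-6) -> WaveFixture:
    """Rotating (spiral-like) wave about an axis.

    phi = omega*t - azimuthal angle about the axis; the flow circulates
    around the axis with speed proportional to the distance from it.
    Nodes on the axis have a degenerate (singular) gradient and are masked.
    """
    axis = np.asarray(axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis must be nonzero")
    axis = axis / np.linalg.norm(axis)
    positions = np.asarray(positions, dtype=float)
    rel = positions - np.asarray(center, dtype=float)
    # orthonormal frame (e1, e2, axis)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ axis) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = rel @ e1
    w = rel @ e2
    rho = np.sqrt(u**2 + w**2)
    mask = rho > core_radius
    if not mask.any():
        raise ValueError("all nodes lie on the rotation axis")
    theta = np.arctan2(w, u)
    times = np.arange(0.0, duration, dt)
    phi = angular_freq * times[:, None] - theta[None, :]
    # grad(theta) = (-w e1 + u e2)/rho^2; v = omega * rho * tangential
    grad = np.zeros_like(positions)
    grad[mask] = ((w[mask][:, None] * e1 - u[mask][:, None] * e2)
                  / (rho[mask] ** 2)[:, None])
    tang = np.zeros_like(positions)
    tang[mask] = ((-w[mask][:, None] * e1 + u[mask][:, None] * e2)
                  / rho[mask][:, None])
    v = np.abs(angular_freq) * rho[:, None] * tang
    dphidt = np.full(positions.shape[0], angular_freq)
    _check_formula(v, grad, dphidt, mask)
    return WaveFixture(positions, _wrap(phi), times, "rotating",
                       {"axis": axis, "center": np.asarray(center, float),
                        "angular_freq": angular_freq},
                       v, mask)


def radial_pattern(positions: np.ndarray, center=(0.0, 0.0, 0.0),
                   sign: str = "sink", speed: float = 10.0,
                   wavelength: float = 60.0, duration: float = 200.0,
                   dt: float = 1.0, core_radius: float = 1e-6) -> WaveFixture:
    """Radial source or sink: waves propagate outward (source) or inward
    (sink) at constant speed along the radius from ``center``."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if sign not in ("source", "sink"):
        raise ValueError("sign must be 'source' or 'sink'")
    positions = np.asarray(positions, dtype=float)
    rel = positions - np.asarray(center, dtype=float)
    r = np.linalg.norm(rel, axis=1)
    mask = r > core_radius
    k = 2.0 * np.pi / wavelength
    omega = speed * k  # rad/ms
    s = +1.0 if sign == "source" else -1.0
    times = np.arange(0.0, duration, dt)
    # source: phi = omega t - k r (outward); sink: phi = omega t + k r
    phi = omega * times[:, None] - s * k * r[None, :]
    rhat = np.zeros_like(positions)
    rhat[mask] = rel[mask] / r[mask][:, None]
    v = s * speed * rhat
    grad = -s * k * rhat
    dphidt = np.full(positions.shape[0], omega)
    _check_formula(v, grad, dphidt, mask)
    return WaveFixture(positions, _wrap(phi), times, sign,
                       {"center": np.asarray(center, float), "speed": speed,
                        "wavelength": wavelength},
                       v, mask)


def metastable_sequence(patterns: list[WaveFixture], segment_ms: float = 400.0,
                        gap_ms: float = 100.0, mod_period_ms: float = 25.0,
                        hemi_lag_ms: float = 8.0, gamma_mid: float = 1.75,
                        gamma_amp: float = 0.75,
                        seed=None) -> WaveFixture:
    """Sequence of wave patterns separated by desynchronized interludes,
    with ground-truth transition times at the gap centers.

    When every pattern is a plane wave the sequence carries a
    detection-grade coherence signature: the wavenumber of each segment
    breathes as ``gamma(t) * k`` with ``gamma = gamma_mid + gamma_amp *
    sin(2 pi t / mod_period_ms)``, shared between hemispheres up to an
    interhemispheric lag of ``hemi_lag_ms``.  Because each hemisphere's
    order parameter is a deterministic aperture function of the
    instantaneous wavenumber, R_L(t) and R_R(t) oscillate strongly and in
    lagged lockstep during a segment — the striped lag signature of the
    interhemispheric cross-correlogram.  During gaps the two hemispheres'
    wavenumbers fluctuate independently (smooth clipped noise of the same
    amplitude), so the coherences keep fluctuating but all interhemispheric
    lag structure vanishes: the inverse lag-variance statistic spikes there
    and nowhere else.

    Patterns other than plane waves are concatenated as-is with
    uniform-random gap phases; such sequences preserve the geometry of the
    constituent patterns but make no guarantee about the sharpness of the
    coherence signature.
    """
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns")
    rng = np.random.default_rng(seed)
    positions = patterns[0].positions
    dt = float(patterns[0].times[1] - patterns[0].times[0])
    seg_n = int(round(segment_ms / dt))
    gap_n = int(round(gap_ms / dt))
    n = positions.shape[0]
    for pat in patterns:
        if pat.positions.shape != positions.shape or not np.allclose(
                pat.positions, positions):
            raise ValueError("all patterns must share the same positions")
    all_plane = all(p.wave_type == "plane" for p in patterns)
    chunks = []
    transition_times = []
    t_cursor = 0
    right = positions[:, 0] > 0

    def smooth_noise(length, width=5, clip=1.5, sd=0.6):
        z = np.convolve(rng.standard_normal(length + 6 * width),
                        np.ones(width) / width, mode="same")[3 * width:3 * width + length]
        return np.clip(z / (z.std() + 1e-12) * sd, -clip, clip)

    for i, pat in enumerate(patterns):
        if all_plane:
            k = np.asarray(pat.truth["wavevector"], dtype=float)
            omega = float(pat.truth["angular_freq"])
            proj = positions @ k
            t_seg = (t_cursor + np.arange(seg_n)) * dt
            ph0 = rng.uniform(0, 2 * np.pi)
            gL = gamma_mid + gamma_amp * np.sin(2 * np.pi * t_seg / mod_period_ms + ph0)
            gR = gamma_mid + gamma_amp * np.sin(
                2 * np.pi * (t_seg - hemi_lag_ms) / mod_period_ms + ph0)
            gamma = np.where(right[None, :], gR[:, None], gL[:, None])
            seg = omega * t_seg[:, None] - gamma * proj[None, :]
        else:
            reps = int(np.ceil(seg_n / pat.phases.shape[0]))
            seg = np.tile(pat.phases, (reps, 1))[:seg_n]
        chunks.append(seg)
        t_cursor += seg_n
        if i < len(patterns) - 1 and gap_n > 0:
            t_gap = (t_cursor + np.arange(gap_n)) * dt
            if all_plane:
                k = np.asarray(pat.truth["wavevector"], dtype=float)
                omega = float(pat.truth["angular_freq"])
                proj = positions @ k
                gamma = np.empty((gap_n, n))
                for sel in (~right, right):
                    z = smooth_noise(gap_n)
                    gamma[:, sel] = (gamma_mid + gamma_amp * 2 / 3 * z)[:, None]
                gap = omega * t_gap[:, None] - gamma * proj[None, :]
            else:
                gap = rng.uniform(-np.pi, np.pi, size=(gap_n, n))
            chunks.append(gap)
            transition_times.append((t_cursor + gap_n / 2.0) * dt)
            t_cursor += gap_n
    phases = _wrap(np.vstack(chunks))
    times = np.arange(phases.shape[0]) * dt
    return WaveFixture(positions, phases, times, "metastable_sequence",
                       {"segment_ms": segment_ms, "gap_ms": gap_ms,
                        "transition_times": np.asarray(transition_times),
                        "patterns": [p.wave_type for p in patterns]})
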