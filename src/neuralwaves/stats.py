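"""Recurrence analysis, surrogate time series, tail fitting, and FC.

Covers the statistical layer of the wave analysis:

* recurrence matrices of velocity-field alignment, tested against
  amplitude-adjusted Fourier (AAFT) surrogates that preserve each channel's
  amplitude distribution and the linear auto-/cross-spectra while destroying
  nonlinear structure;
* maximum-likelihood fits of dwell-time upper tails for five candidate
  families (Pareto, exponentially truncated power law, lognormal,
  exponential, Weibull) with Vuong's test for non-nested model comparison;
* functional-connectivity summaries: raw Pearson FC, FC after hemodynamic
  (BOLD) convolution with optional global signal regression, and band-limited
  amplitude-envelope correlations with leakage orthogonalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate as _integrate
from scipy import optimize, signal, stats as sps

from .dynamics import Trajectory
from .phasefield import VelocityField
from .transitions import DwellTimes

logger = logging.getLogger(__name__)

__all__ = [
    "RecurrenceMatrix",
    "TailFit",
    "alignment_recurrence",
    "aaft_surrogate",
    "recurrence_significance",
    "fit_tail",
    "sample_tail",
    "vuong_test",
    "fc_matrix",
    "bold_convolve",
    "envelope_aec",
    "TAIL_FAMILIES",
]


# ---------------------------------------------------------------------------
# Recurrence of velocity fields
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceMatrix:
    """Frame x frame mean alignment (cosine similarity) of velocity fields."""

    r: np.ndarray  # (F, F), symmetric, unit diagonal where defined
    frame_times: np.ndarray


def alignment_recurrence(vel: VelocityField, frame_stride: int = 1) -> RecurrenceMatrix:
    """Mean-over-nodes cosine similarity between velocity fields at all
    pairs of frames; nodes masked in either frame are excluded pairwise."""
    idx = np.arange(0, vel.v.shape[0], frame_stride)
    if idx.size < 2:
        raise ValueError("need at least 2 frames")
    v = vel.v[idx]  # (F, N, 3)
    m = vel.mask[idx]
    norms = np.linalg.norm(v, axis=2)
    ok = m & (norms > 0)
    unit = np.zeros_like(v)
    unit[ok] = v[ok] / norms[ok][:, None]
    okf = ok.astype(float)
    counts = okf @ okf.T
    # unit vectors are zero at invalid nodes, so the dot products only
    # accumulate over nodes valid in both frames
    sums = np.einsum("ind,jnd->ij", unit, unit)
    with np.errstate(invalid="ignore"):
        r = sums / counts
    empty = counts == 0
    if empty.any():
        logger.warning("recurrence: %d frame pairs share no valid node",
                       int(empty.sum()))
    return RecurrenceMatrix(r, vel.times[idx])


def recurrence_significance(empirical: RecurrenceMatrix,
                            surrogates: list) -> np.ndarray:
    """Signed exceedance mask: +1 where the empirical recurrence is above
    all surrogates, -1 where below all, 0 otherwise."""
    if len(surrogates) < 2:
        raise ValueError("need at least 2 surrogate recurrence matrices")
    stack = np.stack([s.r for s in surrogates])
    if stack.shape[1:] != empirical.r.shape:
        raise ValueError("surrogate shape mismatch")
    hi = np.nanmax(stack, axis=0)
    lo = np.nanmin(stack, axis=0)
    out = np.zeros_like(empirical.r, dtype=int)
    out[empirical.r > hi] = 1
    out[empirical.r < lo] = -1
    return out


# ---------------------------------------------------------------------------
# AAFT surrogates
# ---------------------------------------------------------------------------

def aaft_surrogate(traj: Trajectory, seed=None) -> Trajectory:
    """Amplitude-adjusted Fourier surrogate of a multichannel trajectory.

    Classic AAFT per channel (rank-remap onto a phase-randomized Gaussian
    copy), with one shared random phase sequence applied to every channel so
    that linear cross-spectra are preserved along with each channel's
    amplitude distribution (sorted values are exactly those of the input)
    and power spectrum.
    """
    x = traj.values
    T, n = x.shape
    if T < 64:
        raise ValueError("need at least 64 samples")
    rng = np.random.default_rng(seed)
    # shared random phase rotation with Hermitian symmetry: the DC (and
    # Nyquist, for even T) bins stay untouched so the inverse FFT is real
    nf = T // 2 + 1
    half = np.zeros(nf)
    if T % 2 == 0:
        half[1:-1] = rng.uniform(0, 2 * np.pi, nf - 2)
    else:
        half[1:] = rng.uniform(0, 2 * np.pi, nf - 1)
    rot = np.exp(1j * half)

    out = np.empty_like(x)
    gauss = np.sort(rng.standard_normal(T))
    for ch in range(n):
        col = x[:, ch]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(T, dtype=int)
        ranks[order] = np.arange(T)
        g = gauss[ranks]  # Gaussianized copy with the ranks of the data
        G = np.fft.rfft(g)
        G = G * rot[: G.size]
        g2 = np.fft.irfft(G, n=T)
        order2 = np.argsort(g2, kind="stable")
        ranks2 = np.empty(T, dtype=int)
        ranks2[order2] = np.arange(T)
        out[:, ch] = np.sort(col)[ranks2]
    return Trajectory(traj.times.copy(), out, traj.model,
                      dict(traj.config, surrogate="aaft"))


# ---------------------------------------------------------------------------
# Dwell-time tail fitting
# ---------------------------------------------------------------------------

def _logZ_trunc_powerlaw(alpha: float, lam: float, x0: float) -> float:
    """log of Z = integral_{x0}^inf x^(-alpha) exp(-x/lam) dx."""
    # factor out the integrand value at x0 for numerical stability
    log_f0 = -alpha * np.log(x0) - x0 / lam

    def rel(x):
        return np.exp(-alpha * np.log(x) + alpha * np.log(x0)
                      - (x - x0) / lam)

    val, _ = _integrate.quad(rel, x0, np.inf, limit=200)
    if val <= 0 or not np.isfinite(val):
        return np.inf
    return log_f0 + np.log(val)


def _ll_pareto(params, x, x0):
    (alpha,) = params
    if alpha <= 1:
        return np.full_like(x, -np.inf)
    return (np.log(alpha - 1) - np.log(x0) - alpha * (np.log(x) - np.log(x0)))


def _ll_trunc_powerlaw(params, x, x0):
    alpha, lam = params
    logZ = _logZ_trunc_powerlaw(alpha, lam, x0)
    if not np.isfinite(logZ):
        return np.full_like(x, -np.inf)
    return -alpha * np.log(x) - x / lam - logZ


def _ll_lognormal(params, x, x0):
    mu, sig = params
    logsf = sps.lognorm.logsf(x0, sig, scale=np.exp(mu))
    return sps.lognorm.logpdf(x, sig, scale=np.exp(mu)) - logsf


def _ll_exponential(params, x, x0):
    (scale,) = params
    return -np.log(scale) - (x - x0) / scale


def _ll_weibull(params, x, x0):
    shape, scale = params
    logsf = sps.weibull_min.logsf(x0, shape, scale=scale)
    return sps.weibull_min.logpdf(x, shape, scale=scale) - logsf


# family registry: (loglik fn, param names, bounds in log-space starts)
TAIL_FAMILIES = {
    "pareto": (_ll_pareto, ("alpha",), [(1.0 + 1e-9, 50.0)]),
    "trunc_powerlaw": (_ll_trunc_powerlaw, ("alpha", "lambda"),
                       [(1e-9, 20.0), (1e-3, 1e8)]),
    "lognormal": (_ll_lognormal, ("mu", "sigma"),
                  [(-20.0, 30.0), (1e-4, 20.0)]),
    "exponential": (_ll_exponential, ("scale",), [(1e-9, 1e9)]),
    "weibull": (_ll_weibull, ("shape", "scale"),
                [(1e-3, 50.0), (1e-3, 1e9)]),
}


@dataclass
class TailFit:
    """Maximum-likelihood fit of one family to tail samples above a cutoff."""

    family: str
    params: dict
    loglik: np.ndarray  # per-point log-likelihood of the tail samples
    cutoff: float
    n_tail: int
    converged: bool = True

    @property
    def total_loglik(self) -> float:
        return float(self.loglik.sum())

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.total_loglik

    def report(self) -> str:
        pstr = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return (f"family={self.family} n_tail={self.n_tail} "
                f"cutoff={self.cutoff:g} params[{pstr}] "
                f"loglik={self.total_loglik:.6g} aic={self.aic:.6g} "
                f"converged={self.converged}")


def fit_tail(dwells: DwellTimes | np.ndarray, family: str,
             cutoff: float = 100.0, tol: float = 1e-8) -> TailFit:
    """Fit one distribution family to the dwell-time tail above ``cutoff``.

    Densities are renormalized on [cutoff, inf).  Closed-form estimators are
    used where available (Pareto, exponential); otherwise bounded L-BFGS-B
    with multiple starts.
    """
    x = dwells.durations if isinstance(dwells, DwellTimes) else np.asarray(dwells, float)
    x = x[x >= cutoff]
    if x.size < 20:
        raise ValueError("need >= 20 tail samples above the cutoff")
    if family not in TAIL_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    llfun, names, bounds = TAIL_FAMILIES[family]

    if family == "pareto":
        alpha = 1.0 + x.size / np.log(x / cutoff).sum()
        params = (alpha,)
        converged = True
    elif family == "exponential":
        params = (float(np.mean(x - cutoff)),)
        converged = True
    else:
        mean_x = float(x.mean())
        if family == "trunc_powerlaw":
            starts = [(1.5, mean_x), (0.5, mean_x * 2), (2.5, mean_x * 5)]
        elif family == "lognormal":
            lx = np.log(x)
            starts = [(lx.mean(), max(lx.std(), 0.05)),
                      (lx.mean() - 1, 1.0), (0.0, 2.0)]
        else:  # weibull
            starts = [(1.0, mean_x - cutoff + 1e-3),
                      (0.7, mean_x), (1.5, mean_x / 2)]

        def nll(p):
            ll = llfun(p, x, cutoff)
            if not np.all(np.isfinite(ll)):
                return 1e12
            return -ll.sum()

        best = None
        converged = False
        for p0 in starts:
            res = optimize.minimize(nll, np.asarray(p0, float),
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": tol, "gtol": tol})
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success and np.isfinite(best.fun))
        if not converged:
            logger.warning("tail fit for %s did not converge cleanly", family)
        params = tuple(best.x)

    ll = llfun(params, x, cutoff)
    return TailFit(family, dict(zip(names, params)), ll, cutoff,
                   int(x.size), converged)


def sample_tail(family: str, params: dict, n: int, cutoff: float = 100.0,
                seed=None) -> np.ndarray:
    """Draw samples from a tail family truncated to [cutoff, inf)."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    if family == "pareto":
        return cutoff * u ** (-1.0 / (params["alpha"] - 1.0))
    if family == "exponential":
        return cutoff + rng.exponential(params["scale"], size=n)
    if family == "lognormal":
        dist = sps.lognorm(params["sigma"], scale=np.exp(params["mu"]))
        return dist.isf(u * dist.sf(cutoff))
    if family == "weibull":
        dist = sps.weibull_min(params["shape"], scale=params["scale"])
        return dist.isf(u * dist.sf(cutoff))
    if family == "trunc_powerlaw":
        # exact rejection sampling: Pareto(alpha) proposal with acceptance
        # exp(-(x - cutoff)/lambda) when alpha > 1, shifted-exponential
        # proposal with acceptance (x/cutoff)^(-alpha) otherwise
        alpha, lam = params["alpha"], params["lambda"]
        out = np.empty(n)
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 100)
            if alpha > 1.0:
                cand = cutoff * rng.uniform(size=m) ** (-1.0 / (alpha - 1.0))
                log_acc = -(cand - cutoff) / lam
            else:
                cand = cutoff + rng.exponential(lam, size=m)
                log_acc = -alpha * np.log(cand / cutoff)
            acc = np.log(rng.uniform(size=m)) < log_acc
            take = cand[acc][: n - filled]
            out[filled:filled + take.size] = take
            filled += take.size
        return out
    raise ValueError(f"unknown family {family!r}")


def vuong_test(fitA: TailFit, fitB: TailFit) -> tuple[float, float]:
    """Vuong's non-nested model comparison on identical samples.

    Z = sum(l_i) / (sqrt(n) * sd(l_i)) with l_i the pointwise log-likelihood
    difference A - B; two-sided normal p-value.  Positive Z favors A.
    """
    if fitA.n_tail != fitB.n_tail:
        raise ValueError("fits must be on identical samples")
    li = fitA.loglik - fitB.loglik
    sd = li.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate Vuong test: zero variance of "
                         "pointwise log-likelihood differences")
    z = li.sum() / (np.sqrt(li.size) * sd)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Functional connectivity
# ---------------------------------------------------------------------------

def fc_matrix(traj: Trajectory, variant: str = "raw") -> np.ndarray:
    """Pairwise Pearson correlation matrix of the trajectory channels.

    Constant channels get NaN rows/columns (and a warning); the diagonal is
    set to 1 everywhere.  ``variant`` is a tag recorded by callers (raw /
    bold / bold_gsr / envelope_aec) — the input should already be on the
    corresponding representation.
    """
    x = traj.values
    if x.shape[0] < 30:
        raise ValueError("need >= 30 samples for FC")
    const = np.ptp(x, axis=0) == 0
    if const.any():
        logger.warning("%d constant channel(s) masked in FC", int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(x.T)
    fc[const, :] = np.nan
    fc[:, const] = np.nan
    np.fill_diagonal(fc, 1.0)
    return fc


def _double_gamma_hrf(t_s: np.ndarray, peak_delay: float = 6.0,
                      undershoot_delay: float = 16.0,
                      peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                      ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~5 s), unit sum."""
    h = (sps.gamma.pdf(t_s, peak_delay / peak_disp, scale=peak_disp)
         - ratio * sps.gamma.pdf(t_s, undershoot_delay / undershoot_disp,
                                 scale=undershoot_disp))
    s = h.sum()
    return h / s if s != 0 else h


def _staged_decimation_factors(q: int) -> list[int]:
    factors = []
    while q > 1:
        for f in (10, 13, 12, 11, 9, 8, 7, 6, 5, 4, 3, 2):
            if q % f == 0:
                factors.append(f)
                q //= f
                break
        else:
            factors.append(q)
            q = 1
    return factors


def bold_convolve(traj: Trajectory, gsr: bool = False,
                  target_dt_ms: float = 100.0,
                  hrf_length_s: float = 32.0) -> Trajectory:
    """Approximate the BOLD signal: HRF convolution + antialiased decimation.

    Convolves each channel with a canonical double-gamma hemodynamic
    response function, then decimates to ``target_dt_ms`` (default 0.1 s)
    with a zero-phase Chebyshev Type I IIR antialiasing filter of order 8,
    applied in stages for large factors.  With ``gsr`` the spatial-mean
    (global) signal is regressed out of every channel afterwards.
    """
    dt_ms = traj.dt
    if traj.times[-1] - traj.times[0] < 30_000:
        raise ValueError("need >= 30 s of signal for a meaningful BOLD FC")
    t_hrf = np.arange(0, hrf_length_s, dt_ms / 1000.0)
    hrf = _double_gamma_hrf(t_hrf)
    x = traj.values - traj.values.mean(axis=0, keepdims=True)
    conv = signal.fftconvolve(x, hrf[:, None], mode="full", axes=0)[: x.shape[0]]
    q = int(round(target_dt_ms / dt_ms))
    y = conv
    for f in _staged_decimation_factors(q):
        y = signal.decimate(y, f, n=8, ftype="iir", zero_phase=True, axis=0)
    if gsr:
        g = y.mean(axis=1, keepdims=True)
        design = np.column_stack([np.ones(y.shape[0]), g[:, 0]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        y = y - design @ beta
    times = traj.times[0] + np.arange(y.shape[0]) * target_dt_ms
    return Trajectory(times, y, traj.model,
                      dict(traj.config, bold=True, gsr=gsr))


def envelope_aec(traj: Trajectory, band: tuple[float, float] = (8.0, 13.0),
                 envelope_dt_s: float = 1.0) -> np.ndarray:
    """Orthogonalized amplitude-envelope correlation matrix.

    Band-pass filters each channel, removes zero-lag signal leakage for each
    ordered pair by orthogonalizing one analytic signal against the other,
    computes Hilbert amplitude envelopes, downsamples envelopes to 1 Hz by
    bin averaging, and correlates them; the two orthogonalization directions
    are averaged to give a symmetric matrix.
    """
    dt_s = traj.dt / 1000.0
    fs = 1.0 / dt_s
    if fs < 30.0:
        raise ValueError("sampling rate must be >= 30 Hz for an 8-13 Hz band")
    if band[1] >= fs / 2:
        raise ValueError("band exceeds the Nyquist frequency")
    if band[0] <= 0:
        raise ValueError("band must be positive")
    if traj.times[-1] - traj.times[0] < 60_000:
        raise ValueError("need >= 60 s of signal for envelope correlations")
    x = traj.values - traj.values.mean(axis=0, keepdims=True)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xb = signal.sosfiltfilt(sos, x, axis=0)
    analytic = signal.hilbert(xb, axis=0)
    per_bin = max(1, int(round(envelope_dt_s * fs)))
    n_bins = analytic.shape[0] // per_bin

    def downsample(env):
        return env[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)

    n = x.shape[1]
    env_plain = np.column_stack([downsample(np.abs(analytic[:, j]))
                                 for j in range(n)])
    aec = np.eye(n)
    for i in range(n):
        xi = analytic[:, i]
        denom = np.abs(xi)
        denom[denom == 0] = 1.0
        for j in range(i + 1, n):
            yj = analytic[:, j]
            # component of y orthogonal to x at zero lag (leakage removed)
            y_orth = np.imag(yj * np.conj(xi) / denom)
            e1 = downsample(np.abs(y_orth))
            r1 = np.corrcoef(env_plain[:, i], e1)[0, 1]
            dj = np.abs(yj)
            dj[dj == 0] = 1.0
            x_orth = np.imag(xi * np.conj(yj) / dj)
            e2 = downsample(np.abs(x_orth))
            r2 = np.corrcoef(env_plain[:, j], e2)[0, 1]
            aec[i, j] = aec[j, i] = 0.5 * (r1 + r2)
    return aec
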