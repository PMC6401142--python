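import numpy as np
import pytest

from neuralwaves.dynamics import Trajectory
from neuralwaves.phasefield import VelocityField
from neuralwaves.stats import (
    RecurrenceMatrix,
    aaft_surrogate,
    alignment_recurrence,
    bold_convolve,
    envelope_aec,
    fc_matrix,
    fit_tail,
    recurrence_significance,
    sample_tail,
    vuong_test,
    TAIL_FAMILIES,
)


def _traj(values, dt=1.0):
    return Trajectory(np.arange(values.shape[0]) * dt, values)


def _vel(vectors_by_frame, positions):
    v = np.asarray(vectors_by_frame, dtype=float)
    mask = np.ones(v.shape[:2], dtype=bool)
    return VelocityField(v, mask, np.arange(float(v.shape[0])), positions)


class TestAlignmentRecurrence:
    def test_identical_negated_orthogonal(self, cloud_small):
        n = cloud_small.shape[0]
        ux = np.tile([1.0, 0, 0], (n, 1))
        uy = np.tile([0, 1.0, 0], (n, 1))
        vel = _vel([ux, ux, -ux, uy], cloud_small)
        rec = alignment_recurrence(vel)
        assert rec.r[0, 1] == pytest.approx(1.0)
        assert rec.r[0, 2] == pytest.approx(-1.0)
        assert rec.r[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self, cloud_small, rng):
        n = cloud_small.shape[0]
        v = rng.standard_normal((6, n, 3))
        rec = alignment_recurrence(_vel(v, cloud_small))
        np.testing.assert_allclose(rec.r, rec.r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rec.r), 1.0)


class TestAAFT:
    def test_sorted_values_exact(self, rng):
        x = rng.standard_normal((300, 4)) ** 3
        out = aaft_surrogate(_traj(x), seed=1)
        for ch in range(4):
            np.testing.assert_array_equal(np.sort(out.values[:, ch]),
                                          np.sort(x[:, ch]))

    def test_autocorrelation_preserved_ar1(self):
        rng = np.random.default_rng(8)
        T = 4000
        x = np.zeros(T)
        for t in range(1, T):
            x[t] = 0.9 * x[t - 1] + rng.standard_normal()
        out = aaft_surrogate(_traj(x[:, None]), seed=2).values[:, 0]

        def ac(v, lag):
            v = v - v.mean()
            return np.dot(v[:-lag], v[lag:]) / np.dot(v, v)

        for lag in (1, 5, 10, 20):
            assert abs(ac(out, lag) - ac(x, lag)) < 0.1

    def test_cross_correlation_preserved(self):
        rng = np.random.default_rng(9)
        T = 4000
        common = np.convolve(rng.standard_normal(T + 20), np.ones(10) / 10,
                             "same")[:T]
        a = common + 0.3 * rng.standard_normal(T)
        b = common + 0.3 * rng.standard_normal(T)
        x = np.column_stack([a, b])
        out = aaft_surrogate(_traj(x), seed=3).values
        r_orig = np.corrcoef(a, b)[0, 1]
        r_surr = np.corrcoef(out[:, 0], out[:, 1])[0, 1]
        assert abs(r_surr - r_orig) < 0.1

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((200, 3))
        a = aaft_surrogate(_traj(x), seed=5).values
        b = aaft_surrogate(_traj(x), seed=5).values
        np.testing.assert_array_equal(a, b)


class TestRecurrenceSignificance:
    def test_trivial_cases(self):
        base = RecurrenceMatrix(np.zeros((4, 4)), np.arange(4.0))
        surr = [RecurrenceMatrix(np.zeros((4, 4)), np.arange(4.0))
                for _ in range(3)]
        # empirical equal to a surrogate -> no exceedance
        np.testing.assert_array_equal(
            recurrence_significance(base, surr), np.zeros((4, 4), int))
        hi = RecurrenceMatrix(np.ones((4, 4)), np.arange(4.0))
        out = recurrence_significance(hi, surr)
        np.testing.assert_array_equal(out, np.ones((4, 4), int))

    def test_exchangeable_null_fraction(self, rng):
        """With the empirical matrix drawn from the surrogate ensemble, the
        expected exceedance fraction per tail is 1/(n_surr + 1)."""
        n_surr = 19
        cells = 40 * 40
        draws = rng.standard_normal((n_surr + 1, 40, 40))
        emp = RecurrenceMatrix(draws[0], np.arange(40.0))
        surr = [RecurrenceMatrix(d, np.arange(40.0)) for d in draws[1:]]
        mask = recurrence_significance(emp, surr)
        frac = np.mean(mask != 0)
        expect = 2.0 / (n_surr + 1)
        # binomial sd over 1600 cells ~ 0.007
        assert abs(frac - expect) < 0.03


class TestTailFits:
    @pytest.mark.parametrize("family,params,cutoff", [
        ("exponential", {"scale": 50.0}, 100.0),
        ("pareto", {"alpha": 2.5}, 100.0),
        ("lognormal", {"mu": 5.5, "sigma": 0.8}, 100.0),
        ("weibull", {"shape": 1.5, "scale": 300.0}, 100.0),
        ("trunc_powerlaw", {"alpha": 0.8, "lambda": 150.0}, 20.0),
    ])
    def test_parameter_recovery(self, family, params, cutoff):
        """Mean MLE over independent replicates of n = 5000 tail samples
        recovers the generating parameters within 5% (averaging removes the
        sampling dispersion of weakly identified truncated-family MLEs)."""
        estimates = {k: [] for k in params}
        for rep in range(8):
            x = sample_tail(family, params, n=5000, cutoff=cutoff,
                            seed=7000 + rep)
            fit = fit_tail(x, family, cutoff=cutoff)
            for k in params:
                estimates[k].append(fit.params[k])
        for key, truth in params.items():
            assert np.mean(estimates[key]) == pytest.approx(truth, rel=0.05), (
                f"{family}.{key}")

    def test_truncated_powerlaw_nests_pareto(self):
        x = sample_tail("pareto", {"alpha": 2.2}, n=3000, cutoff=100.0, seed=7)
        pareto = fit_tail(x, "pareto")
        tpl = fit_tail(x, "trunc_powerlaw")
        assert tpl.total_loglik >= pareto.total_loglik - 1e-3
        assert tpl.total_loglik - pareto.total_loglik < 3.0

    def test_too_few_tail_samples(self):
        with pytest.raises(ValueError):
            fit_tail(np.full(10, 200.0), "exponential")

    def test_report_format(self):
        x = sample_tail("exponential", {"scale": 30.0}, 500, seed=1)
        fit = fit_tail(x, "exponential")
        text = fit.report()
        assert "exponential" in text and "loglik" in text


class TestVuong:
    def test_antisymmetry(self):
        x = sample_tail("exponential", {"scale": 60.0}, 2000, seed=11)
        fa = fit_tail(x, "exponential")
        fb = fit_tail(x, "lognormal")
        z1, p1 = vuong_test(fa, fb)
        z2, p2 = vuong_test(fb, fa)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_identical_fits(self):
        x = sample_tail("exponential", {"scale": 60.0}, 1000, seed=12)
        fa = fit_tail(x, "exponential")
        with pytest.raises(ValueError):
            vuong_test(fa, fa)

    def test_prefers_generating_family(self):
        wins = 0
        for rep in range(20):
            x = sample_tail("exponential", {"scale": 80.0}, 2000,
                            cutoff=100.0, seed=100 + rep)
            fa = fit_tail(x, "exponential")
            fb = fit_tail(x, "pareto")
            z, p = vuong_test(fa, fb)
            wins += (z > 0) and (p < 0.05)
        assert wins >= 18


class TestFC:
    def test_duplicated_and_antiphase_channels(self):
        t = np.arange(200.0)
        s = np.sin(0.1 * t)
        x = np.column_stack([s, s, -s])
        fc = fc_matrix(_traj(x))
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(fc, fc.T)

    def test_independent_noise_level(self, rng):
        x = rng.standard_normal((2000, 6))
        fc = fc_matrix(_traj(x))
        off = fc[~np.eye(6, dtype=bool)]
        assert np.abs(off).mean() < 3.0 / np.sqrt(2000) * 2

    def test_constant_channel_masked(self, rng):
        x = np.column_stack([rng.standard_normal(100), np.ones(100)])
        fc = fc_matrix(_traj(x))
        assert np.isnan(fc[0, 1])
        assert fc[1, 1] == 1.0


class TestBold:
    def test_impulse_yields_hrf_peak_near_5s(self):
        T = 40_000  # 40 s at 1 ms
        x = np.zeros((T, 1))
        x[1000, 0] = 1.0
        out = bold_convolve(_traj(x))
        peak_t = out.times[np.argmax(out.values[:, 0])]
        assert 4000.0 < peak_t - 1000.0 < 7000.0
        assert out.times[1] - out.times[0] == pytest.approx(100.0)

    def test_gsr_residual_orthogonal_to_global_mean(self, rng):
        x = rng.standard_normal((40_000, 5)) + rng.standard_normal((40_000, 1))
        out = bold_convolve(_traj(x), gsr=True)
        g = out.values.mean(axis=1)
        assert np.abs(g).max() < 1e-8

    def test_correlated_channels_stay_correlated(self, rng):
        s = np.cumsum(rng.standard_normal(40_000))
        x = np.column_stack([s, s + 1e-6 * rng.standard_normal(40_000)])
        out = bold_convolve(_traj(x))
        assert np.corrcoef(out.values.T)[0, 1] > 0.999

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            bold_convolve(_traj(rng.standard_normal((1000, 2))))


class TestEnvelopeAEC:
    def _band_signal(self, rng, T, dt_s, f=10.0, envelope=None):
        t = np.arange(T) * dt_s
        carrier = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if envelope is None:
            envelope = 1.0
        return carrier * envelope

    def test_scaled_copy_orthogonalizes_to_zero(self, rng):
        dt = 5.0  # ms -> 200 Hz
        T = 14_000  # 70 s
        x = self._band_signal(rng, T, dt / 1000.0)
        traj = _traj(np.column_stack([x, 3.0 * x]), dt=dt)
        aec = envelope_aec(traj)
        assert abs(aec[0, 1]) < 0.2

    def test_common_slow_modulation_detected(self, rng):
        dt = 5.0
        T = 24_000  # 120 s
        t = np.arange(T) * dt / 1000.0
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 0.05 * t)
        a = self._band_signal(rng, T, dt / 1000.0, f=10.0, envelope=env)
        b = self._band_signal(rng, T, dt / 1000.0, f=11.5, envelope=env)
        noise = 0.05 * rng.standard_normal((T, 2))
        aec = envelope_aec(_traj(np.column_stack([a, b]) + noise, dt=dt))
        assert aec[0, 1] > 0.5

    def test_white_noise_near_zero(self, rng):
        dt = 5.0
        x = rng.standard_normal((24_000, 3))
        aec = envelope_aec(_traj(x, dt=dt))
        off = aec[~np.eye(3, dtype=bool)]
        assert np.abs(off).mean() < 0.15

    def test_band_outside_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            envelope_aec(_traj(rng.standard_normal((14_000, 2)), dt=5.0),
                         band=(90.0, 120.0))
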