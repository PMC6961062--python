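import numpy as np
import pytest

from tremorkit import (
    TremorSimParams,
    coherence_ci,
    coherence_confidence_limit,
    msc,
    preprocess_acc,
    preprocess_emg,
    segment_signal,
    simulate_recording,
    split_cosine_taper,
)
from tremorkit.coherence import _split_cosine_window
from tremorkit.exceptions import DegenerateCoherenceError, ParameterError, WindowError

FS = 1000.0


class TestSegmentation:
    def test_counts_and_remainder(self):
        segs = segment_signal(np.arange(30_000), 1024)
        assert len(segs) == 29
        assert all(len(s) == 1024 for s in segs)
        # 29 * 1024 = 29696 -> 304... check: 30000 - 29696 = 304 samples dropped
        np.testing.assert_array_equal(segs[0], np.arange(1024))
        np.testing.assert_array_equal(segs[-1], np.arange(28 * 1024, 29 * 1024))

    def test_exact_fit(self):
        segs = segment_signal(np.arange(1000), 1000)
        assert len(segs) == 1

    def test_window_too_large(self):
        with pytest.raises(WindowError):
            segment_signal(np.arange(1000), 1100)


class TestSplitCosineTaper:
    def test_middle_unchanged(self):
        x = np.ones(1000)
        y = split_cosine_taper(x, 0.1)
        m = 100
        np.testing.assert_array_equal(y[m:-m], 1.0)
        assert np.all(y[:m] < 1.0)

    def test_p_zero_identity(self, rng):
        x = rng.normal(size=256)
        np.testing.assert_array_equal(split_cosine_taper(x, 0.0), x)

    def test_energy_matches_window_formula(self):
        # direct evaluation of the cosine-bell formula, independent arithmetic
        w, p = 1000, 0.1
        m = int(np.ceil(p * w))
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
        expected = 2 * np.sum(ramp**2) + (w - 2 * m)
        y = split_cosine_taper(np.ones(w), p)
        assert np.sum(y**2) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_endpoints(self):
        win = _split_cosine_window(101, 0.25)
        np.testing.assert_allclose(win, win[::-1])
        assert 0 < win[0] < 1

    def test_bad_fraction(self):
        with pytest.raises(ParameterError):
            split_cosine_taper(np.ones(10), 0.6)


class TestConfidenceLimit:
    def test_l2_exact(self):
        assert coherence_confidence_limit(2, 0.05) == pytest.approx(0.95, abs=1e-15)

    def test_l21_value(self):
        # direct evaluation: 1 - 0.05**(1/20)
        assert coherence_confidence_limit(21, 0.05) == pytest.approx(
            1 - 0.05 ** (1 / 20), abs=1e-15
        )
        assert coherence_confidence_limit(21, 0.05) == pytest.approx(0.1391, abs=1e-4)

    def test_strictly_decreasing(self):
        vals = [coherence_confidence_limit(L, 0.05) for L in range(2, 201)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_degenerate(self):
        with pytest.raises(DegenerateCoherenceError):
            coherence_confidence_limit(1, 0.05)


class TestCoherenceCI:
    def test_zero_coherence_low_is_zero(self):
        lo, hi = coherence_ci(0.0, 10)
        assert lo == 0.0
        assert hi > 0.0

    def test_arithmetic_oracle(self):
        # independent re-evaluation of the transform at C=0.5, L=29
        from scipy.stats import norm

        z = norm.ppf(0.975)
        g = np.arctanh(np.sqrt(0.5))
        h = z / np.sqrt(58)
        lo, hi = coherence_ci(0.5, 29)
        assert lo == pytest.approx(np.tanh(g - h) ** 2, abs=1e-12)
        assert hi == pytest.approx(np.tanh(g + h) ** 2, abs=1e-12)

    def test_brackets_estimate(self):
        for c in [0.0, 0.1, 0.5, 0.9, 1.0]:
            lo, hi = coherence_ci(c, 12)
            assert lo <= c <= hi
            assert 0.0 <= lo and hi <= 1.0

    def test_width_shrinks_with_l(self):
        widths = [np.subtract(*coherence_ci(0.5, L)[::-1]) for L in (4, 8, 16, 64)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestMsc:
    def test_self_coherence_is_one(self, rng):
        x = rng.normal(size=8192)
        res = msc(x, x, FS, 1024)
        np.testing.assert_allclose(res.coherence, 1.0, atol=1e-9)

    def test_scale_and_sign_invariance(self, rng):
        x = rng.normal(size=8192)
        res = msc(x, -2.0 * x, FS, 1024)
        np.testing.assert_allclose(res.coherence, 1.0, atol=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        x = rng.normal(size=20_000)
        y = 0.5 * x + rng.normal(size=20_000)
        res = msc(x, y, FS, 512)
        assert np.all(res.coherence >= 0.0)
        assert np.all(res.coherence <= 1.0 + 1e-12)
        assert np.all(res.ci_low <= res.coherence + 1e-12)
        assert np.all(res.coherence <= res.ci_high + 1e-12)

    def test_matches_brute_force_for_two_segments(self, rng):
        # direct evaluation of the defining formula from raw DFT sums
        W = 64
        x = rng.normal(size=2 * W)
        y = 0.7 * x + rng.normal(size=2 * W)
        p = 0.1
        m = int(np.ceil(p * W))
        win = np.ones(W)
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
        win[:m] = ramp
        win[-m:] = ramp[::-1]
        t = np.arange(W)
        ks = np.arange(W // 2 + 1)
        Sxy = np.zeros(len(ks), complex)
        Sxx = np.zeros(len(ks))
        Syy = np.zeros(len(ks))
        for l in range(2):
            xs = (x[l * W : (l + 1) * W] - x[l * W : (l + 1) * W].mean()) * win
            ys = (y[l * W : (l + 1) * W] - y[l * W : (l + 1) * W].mean()) * win
            X = np.array([np.sum(xs * np.exp(-2j * np.pi * k * t / W)) for k in ks])
            Y = np.array([np.sum(ys * np.exp(-2j * np.pi * k * t / W)) for k in ks])
            Sxy += X * np.conj(Y)
            Sxx += np.abs(X) ** 2
            Syy += np.abs(Y) ** 2
        expected = np.abs(Sxy) ** 2 / (Sxx * Syy)
        res = msc(x, y, FS, W)
        np.testing.assert_allclose(res.coherence, expected, rtol=1e-9, atol=1e-9)

    def test_length_mismatch(self, rng):
        with pytest.raises(ParameterError):
            msc(rng.normal(size=100), rng.normal(size=99), FS, 32)

    def test_single_segment_rejected(self, rng):
        with pytest.raises(DegenerateCoherenceError):
            msc(rng.normal(size=100), rng.normal(size=100), FS, 64)

    def test_null_calibration_quick(self):
        # lighter version of the full Monte-Carlo: 10 seeds
        rates = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            res = msc(r.normal(size=60_000), r.normal(size=60_000), FS, 1024)
            rates.append(np.mean(res.coherence[1:] > res.confidence_limit))
        assert 0.02 < np.mean(rates) < 0.08

    def test_detects_shared_oscillator(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rec = simulate_recording(TremorSimParams(seed=seed, coupling=1.0))
            a = preprocess_acc(rec.channel("L-ACC"), FS)
            e = preprocess_emg(rec.channel("L-ECR"), FS)
            res = msc(a, e, FS, 1024)
            i = np.argmin(np.abs(res.freqs - 5.0))
            hits += res.coherence[i] > res.confidence_limit
        assert hits == n_seeds
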