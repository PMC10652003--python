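import numpy as np
import pytest
from scipy.signal import get_window

from pullkin.bicoherence import (
    BicoherenceMap,
    SpectralParams,
    band_max,
    cross_bicoherence,
    mean_map,
    regrid_map,
)
from pullkin.errors import InputError, ParameterError

FPS = 60.0


def coupled_triplet(dur=60.0, seed=1):
    """mode1 at 3 Hz; mode2 carries 2 Hz and a phase-coupled 5 Hz component."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, dur, 1 / FPS)
    phi, psi = rng.uniform(0, 2 * np.pi, 2)
    m1 = np.cos(2 * np.pi * 3 * t + phi)
    m2 = np.cos(2 * np.pi * 2 * t + psi) + np.cos(2 * np.pi * 5 * t + phi + psi)
    return m1, m2


def direct_summation_oracle(m1, m2, f1, f2, window_s=2.0, overlap_s=1.0):
    """Independent bicoherence estimate: manual Hann-windowed FFT per block."""
    nper = int(window_s * FPS)
    step = nper - int(overlap_s * FPS)
    win = get_window("hann", nper)
    i1 = int(round(f1 * window_s))
    i2 = int(round(f2 * window_s))
    num = 0.0 + 0.0j
    aa = bb = 0.0
    for start in range(0, len(m1) - nper + 1, step):
        s1 = (m1[start : start + nper] - m1[start : start + nper].mean()) * win
        s2 = (m2[start : start + nper] - m2[start : start + nper].mean()) * win
        X1, X2 = np.fft.rfft(s1), np.fft.rfft(s2)
        a = X1[i1] * X2[i2]
        b = X2[i1 + i2]
        num += a * np.conj(b)
        aa += abs(a) ** 2
        bb += abs(b) ** 2
    return abs(num) / np.sqrt(aa * bb)


class TestCrossBicoherence:
    def test_phase_coupled_triplet_detected(self):
        m1, m2 = coupled_triplet()
        bmap = regrid_map(cross_bicoherence(m1, m2, FPS))
        assert band_max(bmap, (2.0, 4.0)) > 0.95

    def test_agrees_with_direct_summation_oracle(self):
        m1, m2 = coupled_triplet(seed=5)
        bmap = cross_bicoherence(m1, m2, FPS)
        i = int(np.argmin(np.abs(bmap.f1_grid - 3.0)))
        j = int(np.argmin(np.abs(bmap.f2_grid - 2.0)))
        oracle = direct_summation_oracle(m1, m2, 3.0, 2.0)
        assert bmap.values[i, j] == pytest.approx(oracle, abs=1e-6)

    def test_phase_randomized_null_is_low(self):
        # 5 Hz component re-drawn with independent phase every window breaks
        # the triplet: coupling falls to estimator-noise level
        rng = np.random.default_rng(7)
        t = np.arange(0, 60, 1 / FPS)
        m1 = np.cos(2 * np.pi * 3 * t + rng.uniform(0, 2 * np.pi))
        m2 = np.cos(2 * np.pi * 2 * t + rng.uniform(0, 2 * np.pi))
        block = int(1.0 * FPS)
        for start in range(0, len(t), block):
            seg = slice(start, start + block)
            m2[seg] += np.cos(2 * np.pi * 5 * t[seg] + rng.uniform(0, 2 * np.pi))
        bmap = cross_bicoherence(m1, m2, FPS)
        i = int(np.argmin(np.abs(bmap.f1_grid - 3.0)))
        j = int(np.argmin(np.abs(bmap.f2_grid - 2.0)))
        assert bmap.values[i, j] < 3 / np.sqrt(bmap.n_windows)

    def test_values_bounded_in_unit_interval(self, rng):
        bmap = cross_bicoherence(rng.standard_normal(3600), rng.standard_normal(3600), FPS)
        assert bmap.values.min() >= 0.0 and bmap.values.max() <= 1.0

    def test_amplitude_invariance(self):
        # broadband modes so every bin carries genuine power (bins with no
        # power hold cancellation noise whose ratio is not scale-stable)
        rng = np.random.default_rng(9)
        m1 = rng.standard_normal(3600)
        m2 = rng.standard_normal(3600)
        b1 = cross_bicoherence(m1, m2, FPS)
        b2 = cross_bicoherence(13.0 * m1, 0.2 * m2, FPS)
        np.testing.assert_allclose(b1.values, b2.values, atol=1e-9)

    def test_too_few_windows_raises(self):
        with pytest.raises(InputError, match="window"):
            cross_bicoherence(np.zeros(200), np.zeros(200), FPS)

    def test_white_noise_band_max_null_distribution(self):
        # order-statistic null oracle: each native grid node in the band is
        # (under independence) the magnitude coherence of random complex
        # n-vectors, with squared value ~ Beta(1, n-1); the 95th percentile
        # of the band maximum over m nodes then solves F(x)^m = 0.95
        from scipy.stats import beta

        n_win = 12
        maxima = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = int(13 * FPS)  # 12 windows at 2 s / 1 s overlap
            bmap = regrid_map(cross_bicoherence(r.standard_normal(n), r.standard_normal(n), FPS))
            assert bmap.n_windows == n_win
            maxima.append(band_max(bmap, (2.0, 4.0)))
        m_nodes = 5 * 5  # native 0.5 Hz grid nodes inside [2, 4]^2
        bound = np.sqrt(beta(1, n_win - 1).ppf(0.95 ** (1 / m_nodes)))
        # grid correlation only lowers the observed maximum below the
        # independence bound
        assert np.percentile(maxima, 95) < bound


class TestRegridAndBandMax:
    def _synthetic_map(self, values, f):
        return BicoherenceMap(f.copy(), f.copy(), values, n_windows=10)

    def test_constant_map_unchanged(self):
        f = np.linspace(0, 20, 41)
        out = regrid_map(self._synthetic_map(np.full((41, 41), 0.37), f))
        np.testing.assert_allclose(out.values, 0.37, atol=1e-12)
        assert out.f1_grid[0] == 0.0 and out.f1_grid[-1] == 15.0
        assert np.allclose(np.diff(out.f1_grid), 0.1)

    def test_linear_map_exact_under_bilinear_regrid(self):
        f = np.linspace(0, 20, 41)
        vals = 0.02 * f[:, None] + 0.01 * f[None, :]
        out = regrid_map(self._synthetic_map(vals, f))
        expected = 0.02 * out.f1_grid[:, None] + 0.01 * out.f2_grid[None, :]
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_band_max_single_spike(self):
        f = np.round(np.arange(0, 15.05, 0.1), 10)
        vals = np.zeros((len(f), len(f)))
        vals[30, 25] = 0.9  # (3.0, 2.5) Hz
        m = self._synthetic_map(vals, f)
        assert band_max(m, (2.0, 4.0)) == 0.9
        assert band_max(m, (5.0, 8.0)) == 0.0

    def test_band_max_matches_exhaustive_scan(self):
        m1, m2 = coupled_triplet(seed=2)
        bmap = regrid_map(cross_bicoherence(m1, m2, FPS))
        sel1 = (bmap.f1_grid >= 2) & (bmap.f1_grid <= 4)
        sel2 = (bmap.f2_grid >= 2) & (bmap.f2_grid <= 4)
        oracle = max(
            bmap.values[i, j]
            for i in np.flatnonzero(sel1)
            for j in np.flatnonzero(sel2)
        )
        assert band_max(bmap, (2.0, 4.0)) == pytest.approx(oracle, abs=1e-6)

    def test_band_outside_grid_rejected(self):
        f = np.linspace(0, 5, 11)
        with pytest.raises(ParameterError):
            band_max(self._synthetic_map(np.zeros((11, 11)), f), (2.0, 8.0))

    def test_mean_of_identical_maps_is_identity(self):
        m1, m2 = coupled_triplet(seed=3)
        bmap = regrid_map(cross_bicoherence(m1, m2, FPS))
        avg = mean_map([bmap, bmap, bmap])
        np.testing.assert_allclose(avg.values, bmap.values, atol=1e-12)
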