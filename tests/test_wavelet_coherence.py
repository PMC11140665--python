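"""Eigenvariate, MODWT band-limiting, Welch MSC, FDR matrix thresholding."""

import numpy as np
import pytest
from scipy import signal

from diurnalconn.coherence import (
    CoherenceError,
    CoherenceMatrix,
    RegionalTimeseries,
    coherence_matrix,
    fdr_threshold_matrix,
    first_eigenvariate,
    modwt_bandlimit,
    ms_coherence,
    msc_null_pvalues,
    n_welch_segments,
    nominal_band,
)

TR = 0.72


def _corr(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestEigenvariate:
    def test_single_voxel_identity_up_to_scale(self, rng):
        x = rng.normal(size=50)
        tc = first_eigenvariate(x[None, :])
        assert _corr(tc, x) == pytest.approx(1.0)

    def test_identical_voxels_mean(self, rng):
        x = rng.normal(size=40)
        tc = first_eigenvariate(np.tile(x, (5, 1)))
        assert _corr(tc, x) == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(3, 20))
        tc = first_eigenvariate(X)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        ref = Vt[0] * s[0] / np.sqrt(3)
        if np.dot(ref, X.mean(axis=0)) < 0:
            ref = -ref
        np.testing.assert_allclose(tc, ref, atol=1e-10)

    def test_sign_follows_mean(self, rng):
        X = np.abs(rng.normal(size=(4, 30))) + 1.0
        tc = first_eigenvariate(X)
        assert np.dot(tc, X.mean(axis=0)) > 0

    def test_zero_input(self):
        assert not np.any(first_eigenvariate(np.zeros((3, 10))))


class TestModwt:
    def test_nominal_band_values(self):
        lo, hi = nominal_band(TR)
        assert lo == pytest.approx(1 / (0.72 * 128))
        assert hi == pytest.approx(1 / (0.72 * 8))
        assert (round(lo, 2), round(hi, 2)) == (0.01, 0.17)

    def test_zero_series(self):
        assert not np.any(modwt_bandlimit(np.zeros(1024)))

    def test_length_preserved(self, rng):
        x = rng.normal(size=1000)  # not a multiple of 2**6: exercises padding
        assert modwt_bandlimit(x).shape == x.shape

    def test_details_additive(self, rng):
        # at a padding-free length the selected details plus their complement
        # (levels 1-2 and the level-6 smooth) reconstruct the input exactly
        x = rng.normal(size=1024)
        out = modwt_bandlimit(x)
        everything = modwt_bandlimit(x, levels=(1, 2, 3, 4, 5, 6))
        approx = x - everything  # the level-6 smooth remainder
        np.testing.assert_allclose(
            out + modwt_bandlimit(x, levels=(1, 2)) + approx, x, atol=1e-8
        )

    def test_linearity(self, rng):
        x, y = rng.normal(size=1100), rng.normal(size=1100)
        np.testing.assert_allclose(
            modwt_bandlimit(x + 2.5 * y),
            modwt_bandlimit(x) + 2.5 * modwt_bandlimit(y),
            atol=1e-9,
        )

    def _energy_ratio(self, freq_hz, n=2048):
        t = np.arange(n) * TR
        x = np.sin(2 * np.pi * freq_hz * t)
        y = modwt_bandlimit(x)
        return np.var(y) / np.var(x)

    def test_in_band_sinusoid_retained(self):
        assert self._energy_ratio(0.05) >= 0.8

    def test_out_of_band_sinusoid_suppressed(self):
        assert self._energy_ratio(0.5) <= 0.2

    def test_white_noise_spectrum_concentrated_in_band(self, rng):
        x = rng.normal(size=8192)
        y = modwt_bandlimit(x)
        f, p = signal.welch(y, fs=1 / TR, nperseg=512)
        lo, hi = nominal_band(TR)
        inband = (f >= lo) & (f <= hi)
        assert p[inband].sum() / p.sum() > 0.8

    def test_2d_matches_rowwise(self, rng):
        X = rng.normal(size=(3, 1000))
        out = modwt_bandlimit(X)
        for k in range(3):
            np.testing.assert_allclose(out[k], modwt_bandlimit(X[k]), atol=1e-10)

    def test_short_series_errors(self):
        with pytest.raises(CoherenceError):
            modwt_bandlimit(np.ones(100))


class TestMsCoherence:
    def test_identical_series(self, rng):
        x = rng.normal(size=1024)
        assert ms_coherence(x, x, TR) == pytest.approx(1.0, abs=1e-9)

    def test_linear_filter_invariance(self, rng):
        # a pure delay (linear phase) keeps coherence ~1 away from edges
        x = rng.normal(size=2048)
        y = np.roll(x, 3)
        band = (0.05, 0.3)
        assert ms_coherence(x[16:-16], y[16:-16], TR, band=band) > 0.98

    def test_matches_scipy_welch_coherence(self, rng):
        x = rng.normal(size=1250)
        y = 0.5 * x + rng.normal(size=1250)
        window, overlap = 128, 0.5
        c_pkg = ms_coherence(x, y, TR, band=None, window=window, overlap=overlap)
        f, cxy = signal.coherence(
            x, y, fs=1 / TR, window="hann", nperseg=window,
            noverlap=window // 2, detrend="constant",
        )
        assert c_pkg == pytest.approx(float(cxy[1:].mean()), abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(size=1024)
        y = rng.normal(size=1024) + 0.4 * x
        a = ms_coherence(x, y, TR)
        b = ms_coherence(3.7 * x + 11.0, 0.2 * y - 5.0, TR)
        assert a == pytest.approx(b, abs=1e-10)

    def test_independent_noise_bias_about_1_over_L(self, rng):
        L, window = 8, 64
        vals = [
            ms_coherence(
                rng.normal(size=L * window), rng.normal(size=L * window), 1.0,
                band=(1 / window, 0.5 - 1 / window), window=window, overlap=0.0,
            )
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(1 / L, rel=0.15)

    def test_zero_variance_errors(self, rng):
        with pytest.raises(CoherenceError):
            ms_coherence(np.ones(1024), rng.normal(size=1024), TR)

    def test_too_short_errors(self, rng):
        with pytest.raises(CoherenceError):
            ms_coherence(rng.normal(size=200), rng.normal(size=200), TR)


class TestCoherenceMatrix:
    def test_identical_nodes_near_one(self, rng):
        x = rng.normal(size=1250)
        ts = RegionalTimeseries(np.vstack([x, x + 1e-9 * rng.normal(size=1250), x]), TR)
        m = coherence_matrix(ts)
        off = m.values[np.triu_indices(3, 1)]
        assert (off > 0.999).all()

    def test_two_node_consistency(self, rng):
        x = rng.normal(size=1250)
        y = rng.normal(size=1250) + 0.3 * x
        ts = RegionalTimeseries(np.vstack([x, y]), TR)
        m = coherence_matrix(ts, bandlimit=False, band=(0.05, 0.3))
        direct = ms_coherence(x, y, TR, band=(0.05, 0.3))
        assert m.values[0, 1] == pytest.approx(direct, abs=1e-12)

    def test_structure_and_segments(self, rng):
        ts = RegionalTimeseries(rng.normal(size=(5, 1250)), TR)
        m = coherence_matrix(ts)
        assert m.values.shape == (5, 5)
        np.testing.assert_array_equal(np.diag(m.values), 1.0)
        np.testing.assert_allclose(m.values, m.values.T)
        assert m.n_segments == n_welch_segments(1250) == 18
        assert 0 <= m.values.min() and m.values.max() <= 1

    def test_deterministic(self, rng):
        data = rng.normal(size=(4, 1250))
        a = coherence_matrix(RegionalTimeseries(data, TR))
        b = coherence_matrix(RegionalTimeseries(data.copy(), TR))
        np.testing.assert_array_equal(a.values, b.values)

    def test_one_node_errors(self, rng):
        with pytest.raises(ValueError):
            coherence_matrix(RegionalTimeseries(rng.normal(size=(1, 1250)), TR))


class TestFdrThreshold:
    def _matrix(self, coh_values, L=8):
        n = 5  # 10 unique edges
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = coh_values
        m = m + m.T
        np.fill_diagonal(m, 1.0)
        return CoherenceMatrix(m, L, TR)

    def test_q_one_keeps_all(self, rng):
        vals = rng.uniform(0.1, 0.9, 10)
        m = self._matrix(vals)
        out = fdr_threshold_matrix(m, q=1.0)
        np.testing.assert_allclose(out.values, m.values)

    def test_all_one_retained(self):
        out = fdr_threshold_matrix(self._matrix(np.ones(10)), q=0.05)
        assert (out.values == 1.0).all()

    def test_matches_bh_oracle(self):
        vals = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        L, q = 8, 0.05
        out = fdr_threshold_matrix(self._matrix(vals, L), q=q)
        # hand BH: sort p ascending, find largest k with p_(k) <= k*q/m
        p = (1 - vals) ** (L - 1)
        order = np.argsort(p)
        m_edges = len(p)
        thresh_k = 0
        for k, idx in enumerate(order, start=1):
            if p[idx] <= k * q / m_edges:
                thresh_k = k
        survivors = set(order[:thresh_k])
        kept = set(np.flatnonzero(out.values[np.triu_indices(5, 1)] > 0))
        assert kept == survivors

    def test_subset_of_unthresholded(self, rng):
        vals = rng.uniform(0.0, 1.0, 10)
        m = self._matrix(vals)
        out = fdr_threshold_matrix(m, q=0.05)
        assert out.thresholded
        nonzero = out.values > 0
        np.testing.assert_allclose(out.values[nonzero], m.values[nonzero])

    def test_null_pvalue_formula(self):
        np.testing.assert_allclose(
            msc_null_pvalues(np.array([0.0, 0.5, 1.0]), 8), [1.0, 0.5**7, 0.0]
        )
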