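"""Spectral, coherence, centrality and lagged-correlation feature contracts."""

import numpy as np
import pytest
from scipy.signal.windows import dpss

from preictal.bands import BANDS
from preictal.features import (
    band_coherence_matrices,
    combine_groups,
    eigen_centrality,
    extract_features,
    feature_dim,
    lagged_correlation_extrema,
    multitaper_band_power,
    multitaper_psd,
    parse_feature_name,
    window_grid,
    window_total_counts,
)

FS = 2000.0
N = 8000  # one 4-s window at 2 kS/s


def tone(freq, amp=1.0, phase=0.0, n=N, fs=FS):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestMultitaperPower:
    def test_white_noise_spectrum_flat_across_bands(self, rng):
        acc = np.zeros(len(BANDS))
        for _ in range(100):
            bp = multitaper_band_power(rng.standard_normal((1, N)), FS)
            acc += bp[0]
        acc /= 100
        assert np.all(np.abs(acc - acc.mean()) < 0.10 * acc.mean())

    def test_tone_concentrates_in_its_band(self):
        bp = multitaper_band_power(tone(10.0)[None], FS)[0]
        assert np.all(bp[2] > 100 * np.delete(bp, 2))

    def test_parseval_total_power_of_tone(self):
        A = 2.0
        f, psd = multitaper_psd(tone(100.0, A)[None], FS)
        df = f[1] - f[0]
        assert psd[0].sum() * df == pytest.approx(A**2 / 2, rel=0.05)


class TestCoherence:
    def test_identical_channels_fully_coherent(self, rng):
        x = rng.standard_normal(N)
        C = band_coherence_matrices(np.stack([x, x]), FS)
        assert np.all(C[:, 0, 1] >= 0.99)
        assert np.all(C[:, 0, 0] == 0.0)  # zero diagonal

    def test_independent_channels_show_only_estimator_bias(self, rng):
        vals = []
        for _ in range(100):
            C = band_coherence_matrices(rng.standard_normal((2, N)), FS)
            vals.append(C[:, 0, 1])
        mean = np.mean(vals)
        assert mean < 2.0 / 15.0  # MSC bias ~ 1/K per frequency, K = 15 tapers

    def test_matches_direct_cross_periodogram_oracle(self, rng):
        """4-channel 1-s toy signals vs an independent per-pair loop (<=1e-6)."""
        n, fs = 2000, 2000.0
        x = rng.standard_normal((4, n))
        C = band_coherence_matrices(x, fs)
        # oracle: explicit per-pair, per-frequency multitaper cross-spectra
        w = dpss(n, 8.0, Kmax=15)
        w = w / np.sqrt((w**2).sum(axis=1, keepdims=True))
        f = np.fft.rfftfreq(n, 1 / fs)
        sel = (f > 0) & (f <= 500.0)
        fsel = f[sel]
        X = np.array([[np.fft.rfft(w[k] * x[c])[sel] for k in range(15)] for c in range(4)])
        for bi, (lo, hi) in enumerate(BANDS):
            m = (fsel >= lo) & ((fsel < hi) if bi < 9 else (fsel <= hi))
            for a in range(4):
                for b in range(a + 1, 4):
                    sab = (X[a] * X[b].conj()).sum(axis=0)
                    saa = (np.abs(X[a]) ** 2).sum(axis=0)
                    sbb = (np.abs(X[b]) ** 2).sum(axis=0)
                    msc = np.abs(sab) ** 2 / (saa * sbb)
                    assert abs(C[bi, a, b] - msc[m].mean()) < 1e-6

    def test_zero_variance_channel_zeroed(self, rng):
        x = rng.standard_normal((3, N))
        x[1] = 0.0
        C = band_coherence_matrices(x, FS)
        assert np.all(C[:, 1, :] == 0) and np.all(C[:, :, 1] == 0)
        assert np.all((C >= 0) & (C <= 1))


class TestEigenCentrality:
    def test_complete_graph_spectrum(self):
        n = 7
        M = np.ones((n, n)) - np.eye(n)
        lam, v = eigen_centrality(M)
        assert lam == pytest.approx(n - 1)
        assert np.allclose(v, 1 / np.sqrt(n))

    def test_zero_matrix_convention(self):
        lam, v = eigen_centrality(np.zeros((4, 4)))
        assert lam == 0.0
        assert v.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        for _ in range(20):
            A = rng.standard_normal((8, 8))
            M = (A + A.T) / 2
            lam, v = eigen_centrality(M)
            w, V = np.linalg.eig(M)
            k = np.argmax(w.real)
            assert lam == pytest.approx(w[k].real, abs=1e-10)
            vv = V[:, k].real
            vv = vv / np.linalg.norm(vv)
            if vv[np.argmax(np.abs(vv))] < 0:
                vv = -vv
            assert np.allclose(v, vv, atol=1e-8)

    def test_nonnegative_matrix_gives_nonnegative_unit_centrality(self, rng):
        M = rng.uniform(0, 1, (10, 10))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        lam, v = eigen_centrality(M)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.all(v >= -1e-12)

    def test_asymmetric_input_rejected(self):
        M = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            eigen_centrality(M)


class TestWindowCounts:
    def test_window_sums_and_overlap_semantics(self):
        counts = np.zeros((2, 8000 * 3), dtype=int)  # 12 s of 0.5 ms bins
        counts[:, 8000] = 1  # event at t = 4 s, shared by windows starting at 2 and 4 s
        grid = window_grid(12.0)
        tot = window_total_counts(counts, 5e-4, grid)
        assert tot[0].tolist() == [0, 0]
        assert tot[1].tolist() == [1, 1]
        assert tot[2].tolist() == [1, 1]
        assert tot[3].tolist() == [0, 0]

    def test_partial_trailing_window_dropped(self):
        grid = window_grid(9.0)  # a window starting at 6 s would overrun 9 s
        assert grid.starts.tolist() == [0.0, 2.0, 4.0]


class TestLaggedCorrelation:
    def test_identity_pair_peaks_at_lag_zero(self, rng):
        x = rng.standard_normal(1000)
        R = lagged_correlation_extrema(np.stack([x, x]), 50)
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 0] == 0.0

    def test_delayed_copy_recovered_at_shift(self, rng):
        x = rng.standard_normal(2000)
        d = 20
        y = np.roll(x, d)
        R = lagged_correlation_extrema(np.stack([x[100:-100], y[100:-100]]), 50)
        assert R[0, 1] == pytest.approx(1.0, abs=0.01)

    def test_anticorrelated_pair_keeps_sign(self, rng):
        x = rng.standard_normal(500)
        R = lagged_correlation_extrema(np.stack([x, -x]), 10)
        assert R[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_channel_zeroed(self, rng):
        x = np.stack([rng.standard_normal(300), np.zeros(300)])
        R = lagged_correlation_extrema(x, 10)
        assert np.all(R == 0)

    def test_matches_naive_per_lag_pearson(self, rng):
        """FFT path vs a brute-force truncated-support Pearson loop."""
        x = rng.standard_normal((3, 200))
        L = 7
        R = lagged_correlation_extrema(x, L)
        for a in range(3):
            for b in range(a + 1, 3):
                best = 0.0
                for l in range(-L, L + 1):
                    if l >= 0:
                        u, v = x[a, l:], x[b, : 200 - l]
                    else:
                        u, v = x[a, : 200 + l], x[b, -l:]
                    r = np.corrcoef(u, v)[0, 1]
                    if abs(r) > abs(best):
                        best = r
                assert R[a, b] == pytest.approx(best, abs=1e-10)


class TestAssembly:
    def test_feature_dims_match_paper_scale(self):
        assert feature_dim("lfp_power", 96) == 960
        assert feature_dim("mua_count", 96) == 96
        assert feature_dim("lfp_coherence", 16) == 10 * (16 + 3)
        assert feature_dim("mua_correlation", 16) == 3 * (16 + 1)

    def test_extracted_frames_consistent(self, small_streams):
        frames = extract_features(small_streams)
        ch = small_streams.lfp.signal.shape[0]
        n = len(frames["lfp_power"])
        for g, df in frames.items():
            assert len(df) == n
            assert df.shape[1] == feature_dim(g, ch)
            assert np.isfinite(df.to_numpy()).all()
        full = combine_groups(frames)
        assert full.shape[1] == sum(feature_dim(g, ch) for g in frames)

    def test_mean_var_of_constant_coherence_matrix(self):
        # all-c off-diagonal matrix -> mean c, variance 0 (computed via assembly path)
        from preictal.features import _coherence_features

        C = np.full((1, 5, 5), 0.3)
        for i in range(5):
            C[0, i, i] = 0.0
        out = _coherence_features(C)
        ch = 5
        assert out[1 + ch] == pytest.approx(0.3)
        assert out[2 + ch] == pytest.approx(0.0)

    def test_channel_permutation_equivariance(self, rng):
        x = rng.standard_normal((4, N))
        perm = np.array([2, 0, 3, 1])
        C1 = band_coherence_matrices(x, FS)
        C2 = band_coherence_matrices(x[perm], FS)
        for b in range(len(BANDS)):
            assert np.allclose(C2[b], C1[b][np.ix_(perm, perm)], atol=1e-12)
            l1, _ = eigen_centrality(C1[b])
            l2, _ = eigen_centrality(C2[b])
            assert l1 == pytest.approx(l2, abs=1e-10)

    def test_parse_feature_name_roundtrip(self):
        t = parse_feature_name("pow|b3|c7")
        assert (t["group"], t["band"], t["channel"]) == ("lfp_power", 3, 7)
        t = parse_feature_name("coh|b9|ev|c0")
        assert (t["group"], t["band"], t["kind"], t["channel"]) == ("lfp_coherence", 9, "ev", 0)
        t = parse_feature_name("mcorr|env|lam")
        assert (t["group"], t["source"]) == ("mua_correlation", "env")
        with pytest.raises(ValueError):
            parse_feature_name("bogus|x")

    def test_artifact_windows_excluded(self, small_streams):
        import dataclasses

        streams = dataclasses.replace(small_streams, artifact_intervals=[(10.0, 14.0)])
        frames = extract_features(streams, groups=("mua_count",))
        t = frames["mua_count"].index.to_numpy()
        assert not np.any((t + 4.0 > 10.0) & (t < 14.0))
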