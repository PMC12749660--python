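import numpy as np
import pytest
from scipy import signal as sg

import neurogut as ng
from conftest import brute_global_efficiency, random_weighted_graph


class TestWelchCrossSpectra:
    def test_matches_scipy_csd(self, rng):
        x = rng.standard_normal((3, 5000))
        rec = ng.EEGRecording(x, 500.0, ["C3", "C4", "Cz"])
        cs = ng.welch_cross_spectra(rec)
        _, S12 = sg.csd(x[0], x[1], fs=500, window="hann", nperseg=500, noverlap=250,
                        detrend="linear")
        # scipy computes conj(X_i) X_j; the contract here is X_i conj(X_j)
        assert np.allclose(cs.S[0, 1], np.conj(S12), atol=1e-12)
        _, S11 = sg.welch(x[0], fs=500, window="hann", nperseg=500, noverlap=250,
                          detrend="linear")
        assert np.allclose(cs.S[0, 0].real, S11, atol=1e-12)

    def test_duplicated_channel_cross_equals_auto(self, rng):
        x = rng.standard_normal(5000)
        rec = ng.EEGRecording(np.vstack([x, x]), 500.0, ["C3", "C4"])
        cs = ng.welch_cross_spectra(rec)
        assert np.allclose(cs.S[0, 1], cs.S[0, 0])
        assert np.allclose(cs.S[0, 1].imag, 0.0, atol=1e-15)

    def test_tone_concentrates_power(self):
        t = np.arange(0, 20, 1 / 500)
        rec = ng.EEGRecording(np.sin(2 * np.pi * 10 * t)[None].repeat(2, 0), 500.0, ["C3", "C4"])
        cs = ng.welch_cross_spectra(rec)
        P = cs.S[0, 0].real
        peak = P[np.argmin(np.abs(cs.freqs - 10.0))]
        assert peak >= 100 * np.median(P)

    def test_hermitian_each_bin(self, noise_recording):
        cs = ng.welch_cross_spectra(noise_recording)
        assert np.allclose(cs.S, np.conj(cs.S.transpose(1, 0, 2)))

    def test_independent_noise_coherence_small(self, rng):
        # 300 s at 500 Hz -> K = 599 segments; per-bin |C| scale ~ 1/sqrt(K_eff)
        # ~ 0.043, and the expected max over 251 bins is sqrt(2 ln 251 / K_eff)
        # ~ 0.14 by extreme-value statistics
        x = rng.standard_normal((2, 150000))
        rec = ng.EEGRecording(x, 500.0, ["C3", "C4"])
        cs = ng.welch_cross_spectra(rec)
        ratio = np.abs(cs.S[0, 1]) / np.sqrt(cs.S[0, 0].real * cs.S[1, 1].real)
        assert ratio.mean() < 0.05
        assert ratio.max() < 0.15

    def test_too_short_recording_rejected(self, rng):
        rec = ng.EEGRecording(rng.standard_normal((2, 600)), 500.0, ["C3", "C4"])
        with pytest.raises(ValueError, match="shorter"):
            ng.welch_cross_spectra(rec)


class TestICOH:
    def test_identical_channels_zero(self, rng):
        x = rng.standard_normal(30000)
        rec = ng.EEGRecording(np.vstack([x, x]), 500.0, ["C3", "C4"])
        for band in ("delta", "alpha", "gamma", "all"):
            W = ng.icoh(ng.welch_cross_spectra(rec), band)
            assert W.W[0, 1] < 1e-10

    def test_quadrature_pair_unity(self):
        # slightly detuned tone so window leakage fills every in-band bin
        t = np.arange(0, 60, 1 / 500)
        rec = ng.EEGRecording(
            np.vstack([np.sin(2 * np.pi * 9.7 * t), np.cos(2 * np.pi * 9.7 * t)]),
            500.0, ["C3", "C4"])
        W = ng.icoh(ng.welch_cross_spectra(rec), "alpha")
        assert W.W[0, 1] > 0.99

    def test_zero_lag_mixing_suppressed(self, rng):
        # x vs x+noise: high coherence magnitude, near-zero imaginary part
        x = rng.standard_normal(30000)
        y = x + rng.standard_normal(30000)
        rec = ng.EEGRecording(np.vstack([x, y]), 500.0, ["C3", "C4"])
        cs = ng.welch_cross_spectra(rec)
        sel = (cs.freqs >= 7) & (cs.freqs <= 12)
        coh = np.abs(cs.S[0, 1, sel]) / np.sqrt(cs.S[0, 0, sel].real * cs.S[1, 1, sel].real)
        W = ng.icoh(cs, "alpha")
        assert coh.mean() > 0.5
        assert W.W[0, 1] < 0.12  # at the Welch estimator's bias floor

    def test_amplitude_scaling_invariance(self, noise_recording):
        W1 = ng.icoh(ng.welch_cross_spectra(noise_recording), "alpha").W
        scaled = ng.EEGRecording(noise_recording.data * np.array([[3.7], [1.0], [0.2]]),
                                 500.0, noise_recording.labels)
        W2 = ng.icoh(ng.welch_cross_spectra(scaled), "alpha").W
        assert np.allclose(W1, W2, atol=1e-12)

    def test_bounds_and_zero_diagonal(self, noise_recording):
        W = ng.icoh(ng.welch_cross_spectra(noise_recording), "all").W
        assert W.min() >= 0 and W.max() <= 1
        assert np.allclose(np.diag(W), 0.0)

    def test_empty_band_rejected(self, noise_recording):
        cs = ng.welch_cross_spectra(noise_recording)
        with pytest.raises(ValueError, match="no frequency bins"):
            ng.icoh(cs, ng.BandSpec("narrow", 10.2, 10.4))


class TestPairsCount:
    @pytest.mark.parametrize("n,expected", [(21, 210), (2, 1), (6, 15)])
    def test_known_counts(self, n, expected):
        assert ng.pairs_count(n) == expected

    def test_matches_enumeration(self):
        import itertools

        for n in range(2, 12):
            assert ng.pairs_count(n) == len(list(itertools.combinations(range(n), 2)))

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            ng.pairs_count(1)


class TestGraphMetrics:
    def test_complete_graph_unit_weights(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert ng.global_efficiency(W) == pytest.approx(1.0)
        assert np.allclose(ng.local_efficiency(W), 1.0)
        assert ng.transitivity(W) == pytest.approx(1.0)

    def test_three_node_path(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert ng.global_efficiency(W) == pytest.approx(5 / 6)
        assert ng.transitivity(W) == 0.0

    def test_two_nodes_weight_w(self):
        assert ng.global_efficiency(np.array([[0, 0.37], [0.37, 0]])) == pytest.approx(0.37)

    def test_star_graph_zero_local_efficiency(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        assert np.allclose(ng.local_efficiency(W), 0.0)

    def test_unit_triangle_transitivity(self):
        tri = np.ones((3, 3)) - np.eye(3)
        assert ng.transitivity(tri) == pytest.approx(1.0)

    def test_oracle_equivalence_random_graphs(self, rng):
        for _ in range(30):
            W = random_weighted_graph(rng)
            assert ng.global_efficiency(W) == pytest.approx(brute_global_efficiency(W), abs=1e-12)
            le = ng.local_efficiency(W)
            for i in range(W.shape[0]):
                nb = np.flatnonzero(W[i] > 0)
                expect = 0.0 if nb.size < 2 else brute_global_efficiency(W[np.ix_(nb, nb)])
                assert le[i] == pytest.approx(expect, abs=1e-12)

    def test_transitivity_matches_triple_enumeration(self, rng):
        for _ in range(20):
            W = random_weighted_graph(rng, max_nodes=5)
            n = W.shape[0]
            k = (W > 0).sum(axis=1)
            den = float((k * (k - 1)).sum())
            num = sum(
                (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
                for i in range(n) for j in range(n) for h in range(n)
                if len({i, j, h}) == 3 and W[i, j] > 0 and W[i, h] > 0 and W[j, h] > 0
            )
            expect = 0.0 if den == 0 else num / den
            assert ng.transitivity(W) == pytest.approx(expect, abs=1e-9)

    def test_global_efficiency_monotone_under_edge_addition(self, rng):
        # a new positive edge can only shorten shortest paths, so GE never
        # drops; T and LE are *not* monotone (a new edge can grow the degree
        # denominator without closing any triangle)
        for _ in range(10):
            W = (random_weighted_graph(rng, max_nodes=6) > 0).astype(float)
            zeros = np.argwhere((W == 0) & ~np.eye(W.shape[0], dtype=bool))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            W2 = W.copy()
            W2[i, j] = W2[j, i] = 1.0
            assert ng.global_efficiency(W2) >= ng.global_efficiency(W) - 1e-12

    def test_transitivity_not_monotone_counterexample(self):
        # triangle plus isolated node: attaching the node adds degree mass but
        # no triangle, so weighted transitivity strictly decreases
        W = np.zeros((4, 4))
        W[:3, :3] = 1.0 - np.eye(3)
        W2 = W.copy()
        W2[0, 3] = W2[3, 0] = 1.0
        assert ng.transitivity(W2) < ng.transitivity(W)

    def test_network_metrics_bundle(self, noise_recording):
        W = ng.icoh(ng.welch_cross_spectra(noise_recording), "alpha")
        nm = ng.network_metrics(W)
        assert 0 <= nm.GE <= 1 and 0 <= nm.T <= 1
        assert nm.LE.shape == (3,)
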