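"""Parcel averaging, coherence estimation, bands, and top-K edges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticoh.spectral import (BANDS, ParcelMap, average_by_parcel,
                               band_average, coherence, coherence_matrix,
                               cross_spectra, pair_count, top_k_edges)


def simple_map(assign, hemis=None):
    labels = sorted(set(assign))
    hemis = hemis or {l: ("right" if l.endswith("R") else "left")
                      for l in labels}
    return ParcelMap(parcel_of_patch=np.array(assign, dtype=object),
                     hemisphere_of_parcel=hemis)


class TestAverageByParcel:
    def test_identical_waveforms_pass_through(self):
        x = np.random.default_rng(0).normal(size=100)
        J = np.tile(x, (4, 1))
        pm = simple_map(["A_R"] * 4)
        out, labels = average_by_parcel(J, pm)
        assert labels == ["A_R"]
        np.testing.assert_allclose(out[0], x)

    def test_signed_cancellation(self):
        x = np.random.default_rng(1).normal(size=50)
        J = np.stack([x, -x])
        out, _ = average_by_parcel(J, simple_map(["A_R", "A_R"]))
        np.testing.assert_allclose(out[0], 0.0, atol=1e-14)

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(2)
        J = rng.normal(size=(10, 64))
        assign = [f"P{i % 3}_R" for i in range(10)]
        out, labels = average_by_parcel(J, simple_map(assign))
        for k, lab in enumerate(labels):
            members = [i for i in range(10) if assign[i] == lab]
            expected = np.zeros(64)
            for i in members:
                expected += J[i]
            np.testing.assert_allclose(out[k], expected / len(members))

    def test_empty_parcel_excluded_with_warning(self, caplog):
        J = np.ones((2, 10))
        pm = ParcelMap(parcel_of_patch=np.array(["A_R", "A_R"], dtype=object),
                       hemisphere_of_parcel={"A_R": "right", "B_L": "left"})
        with caplog.at_level("WARNING", logger="corticoh.spectral"):
            out, labels = average_by_parcel(J, pm)
        assert labels == ["A_R"]
        assert "no member patches" in caplog.text

    def test_parcel_map_requires_hemispheres(self):
        with pytest.raises(ValueError, match="hemisphere"):
            ParcelMap(parcel_of_patch=np.array(["A"], dtype=object),
                      hemisphere_of_parcel={})


class TestCrossSpectra:
    def test_one_second_epoch_gives_1hz_bins(self):
        x = np.random.default_rng(0).normal(size=(3, 250))
        freqs, S_xx, _, _ = cross_spectra(x, x, fs=250.0)
        np.testing.assert_array_equal(freqs, np.arange(1, 71))
        assert S_xx.shape == (70,)

    def test_pure_sine_concentrates_in_its_bin(self):
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        freqs, S_xx, _, _ = cross_spectra(x, x, fs=250.0)
        assert S_xx[freqs == 10] > 1e3 * S_xx[freqs != 10].max()

    def test_self_cross_spectrum_is_autospectrum(self):
        x = np.random.default_rng(1).normal(size=(5, 250))
        _, S_xx, _, S_xy = cross_spectra(x, x, fs=250.0)
        np.testing.assert_allclose(S_xy.imag, 0.0, atol=1e-9)
        np.testing.assert_allclose(S_xy.real, S_xx, rtol=1e-12)

    def test_bins_above_nyquist_rejected(self):
        x = np.zeros((2, 100))
        with pytest.raises(ValueError, match="Nyquist"):
            cross_spectra(x, x, fs=100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shape"):
            cross_spectra(np.zeros((2, 250)), np.zeros((3, 250)), fs=250.0)


class TestCoherence:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(0).normal(size=(8, 250))
        _, S_xx, S_yy, S_xy = cross_spectra(x, x, fs=250.0)
        np.testing.assert_allclose(coherence(S_xx, S_yy, S_xy), 1.0,
                                   atol=1e-12)

    def test_single_epoch_degenerates_to_one_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 250))
        y = rng.normal(size=(1, 250))
        _, S_xx, S_yy, S_xy = cross_spectra(x, y, fs=250.0)
        with caplog.at_level("WARNING", logger="corticoh.spectral"):
            c = coherence(S_xx, S_yy, S_xy, n_epochs=1)
        np.testing.assert_allclose(c, 1.0, atol=1e-9)
        assert "single epoch" in caplog.text

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 250))
        y = rng.normal(size=(20, 250))
        _, S_xx, S_yy, S_xy = cross_spectra(x, y, fs=250.0)
        c = coherence(S_xx, S_yy, S_xy)
        assert np.all(c >= 0) and np.all(c <= 1)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 250))
        y = rng.normal(size=(6, 250))
        _, S_xx, S_yy, S_xy = cross_spectra(x, y, fs=250.0)
        _, S_xx2, S_yy2, S_xy2 = cross_spectra(x, scale * y, fs=250.0)
        np.testing.assert_allclose(coherence(S_xx2, S_yy2, S_xy2),
                                   coherence(S_xx, S_yy, S_xy),
                                   rtol=1e-12, atol=1e-12)

    def test_shared_sine_plus_noise_matches_prediction(self):
        # x = s + n1, y = s + n2 at the sine's bin: coherence ->
        # P_s / (P_s + P_n_bin); checked against a long-run simulation
        fs, n = 250.0, 250
        t = np.arange(n) / fs
        s_amp, noise_sd = 1.0, 1.0

        def run(m, seed):
            rng = np.random.default_rng(seed)
            s = s_amp * np.sin(2 * np.pi * 10 * t)
            x = s + rng.normal(0, noise_sd, (m, n))
            y = s + rng.normal(0, noise_sd, (m, n))
            freqs, S_xx, S_yy, S_xy = cross_spectra(x, y, fs)
            return coherence(S_xx, S_yy, S_xy)[freqs == 10][0]

        long_run = run(20000, 0)          # oracle: near-asymptotic estimate
        got = run(100, 1)
        assert got == pytest.approx(long_run, abs=0.1)
        # analytic check of the oracle itself
        P_s = np.abs(np.fft.rfft(s_amp * np.sin(2 * np.pi * 10 * t))[10]) ** 2
        P_n = noise_sd ** 2 * n  # white noise: flat expected periodogram
        assert long_run == pytest.approx(P_s / (P_s + P_n), abs=0.02)

    def test_negative_autospectrum_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            coherence(np.array([-1.0]), np.array([1.0]), np.array([1.0]))


class TestBandAverage:
    def test_constant_coherence(self):
        out = band_average(np.full(70, 0.42))
        np.testing.assert_allclose(out, 0.42)

    def test_single_alpha_bin(self):
        c = np.zeros(70)
        c[np.arange(1, 71) == 10] = 1.0
        out = band_average(c)
        names = list(BANDS)
        np.testing.assert_allclose(out[names.index("alpha")], 1 / 5)
        for b, name in enumerate(names):
            if name != "alpha":
                assert out[b] == 0.0

    def test_linear_ramp_matches_bin_enumeration(self):
        freqs = np.arange(1, 71)
        c = freqs / 70.0
        out = band_average(c)
        for b, (name, (lo, hi)) in enumerate(BANDS.items()):
            members = [f / 70.0 for f in range(lo, hi + 1)]
            assert out[b] == pytest.approx(sum(members) / len(members))

    def test_band_with_no_defined_bins_is_nan(self):
        c = np.full(70, np.nan)
        c[15] = 0.5  # 16 Hz: beta only
        out = band_average(c)
        names = list(BANDS)
        assert np.isnan(out[names.index("alpha")])
        assert out[names.index("beta")] == pytest.approx(0.5)

    def test_bands_tile_1_to_70(self):
        covered = sorted(f for lo, hi in BANDS.values()
                         for f in range(lo, hi + 1))
        assert covered == list(range(1, 71))


class TestPairCount:
    @pytest.mark.parametrize("n,expected", [
        (2400, 2_878_800), (80, 3160), (1, 0), (2, 1),
    ])
    def test_values(self, n, expected):
        assert pair_count(n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            pair_count(0)


class TestCoherenceMatrix:
    def test_identical_signals_all_ones(self):
        x = np.random.default_rng(0).normal(size=(5, 250))
        ep = np.stack([x, x], axis=1)  # 2 parcels, same signal
        res = coherence_matrix(ep, ["A_R", "B_L"], fs=250.0)
        np.testing.assert_allclose(res.per_freq, 1.0, atol=1e-9)
        np.testing.assert_allclose(res.per_band, 1.0, atol=1e-9)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        ep = rng.normal(size=(10, 4, 250))
        res = coherence_matrix(ep, list("ABCD"), fs=250.0)
        np.testing.assert_array_equal(res.per_freq,
                                      np.swapaxes(res.per_freq, 0, 1))
        for i in range(4):
            np.testing.assert_allclose(res.per_freq[i, i], 1.0)

    def test_independent_noise_off_diagonal_small(self):
        rng = np.random.default_rng(2)
        ep = rng.normal(size=(200, 4, 250))
        res = coherence_matrix(ep, list("ABCD"), fs=250.0)
        iu = np.triu_indices(4, k=1)
        assert res.per_band[iu].max() < 0.25

    def test_right_then_left_block_layout(self):
        rng = np.random.default_rng(3)
        labels_r = ["P0_R", "P1_R", "P2_R"]
        labels_l = ["P3_L", "P4_L"]
        assign = labels_r + labels_l
        pm = simple_map(assign)
        ordered = pm.ordered_labels()
        assert ordered[:3] == labels_r and ordered[3:] == labels_l
        J = rng.normal(size=(6, 5, 250))
        parcel_ep, labels = average_by_parcel(J, pm)
        res = coherence_matrix(parcel_ep, labels, fs=250.0)
        # upper-left 3x3 block holds exactly the right-intra pairs
        assert res.parcels[:3] == labels_r

    def test_single_parcel_rejected(self):
        with pytest.raises(ValueError, match="2 parcels"):
            coherence_matrix(np.zeros((3, 1, 250)), ["A"], fs=250.0)

    def test_null_coherence_decays_with_epoch_count(self):
        # mean off-diagonal coherence of independent noise shrinks as the
        # epoch count doubles
        rng = np.random.default_rng(4)
        means = []
        for n_ep in [2, 4, 8, 16, 32, 64, 128, 256]:
            ep = rng.normal(size=(n_ep, 3, 250))
            res = coherence_matrix(ep, list("ABC"), fs=250.0)
            iu = np.triu_indices(3, k=1)
            means.append(np.nanmean(res.per_band[iu]))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestTopKEdges:
    def _result(self, n_parcels=4, n_ep=8, seed=0, planted=None):
        rng = np.random.default_rng(seed)
        ep = rng.normal(size=(n_ep, n_parcels, 250))
        if planted is not None:
            i, j = planted
            t = np.arange(250) / 250.0
            shared = np.sin(2 * np.pi * 10 * t + rng.uniform(
                0, 2 * np.pi, size=(n_ep, 1)))
            ep[:, i] += 5 * shared
            ep[:, j] += 5 * shared
        labels = [f"P{i}_R" for i in range(n_parcels)]
        return coherence_matrix(ep, labels, fs=250.0)

    def test_k_exceeding_pairs_returns_all(self):
        res = self._result()
        edges = top_k_edges(res, k=1000)
        assert len(edges) == pair_count(4) * len(res.band_names)

    def test_planted_pair_ranks_first_in_its_band(self):
        res = self._result(planted=(0, 3))
        edges = [e for e in top_k_edges(res, k=3) if e[0] == "alpha"]
        assert {edges[0][1], edges[0][2]} == {"P0_R", "P3_R"}

    def test_planted_recovery_rate_across_replicates(self):
        # band-limited coupled pair lands in its band's top-10 in >=95%
        # of 100 seeded replicates
        hits = 0
        for seed in range(100):
            res = self._result(n_parcels=20, n_ep=20, seed=seed,
                               planted=(2, 17))
            top = [e for e in top_k_edges(res, k=10) if e[0] == "alpha"]
            hits += any({e[1], e[2]} == {"P2_R", "P17_R"} for e in top)
        assert hits >= 95

    def test_sorted_descending_with_deterministic_ties(self):
        res = self._result()
        res.per_band[:] = 0.5  # force total ties
        edges = top_k_edges(res, k=3, pooled=True)
        assert [e[0] for e in edges] == ["delta"] * 3
        assert [(e[1], e[2]) for e in edges] == [
            ("P0_R", "P1_R"), ("P0_R", "P2_R"), ("P0_R", "P3_R")]

    def test_pooled_vs_per_band_counts(self):
        res = self._result()
        assert len(top_k_edges(res, k=2)) == 2 * len(res.band_names)
        assert len(top_k_edges(res, k=2, pooled=True)) == 2

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k"):
            top_k_edges(self._result(), k=0)
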