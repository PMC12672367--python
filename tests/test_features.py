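"""Per-epoch feature base: spectra, PAC, coherence, complexity, CATCH-22."""

import numpy as np
import pytest
from scipy import signal as sg

from somnifold.features import (CATCH22_NAMES, SpectralConfig,
                                catch22_features, compute_feature_matrix,
                                compute_psd, entropy_rate, feature_names,
                                lz76_complexity, pac, spectral_features,
                                spectral_slope, temporal_coherence)
from somnifold.features.complexity import _lz76_reference
from somnifold.features import _fast
from somnifold.io import EEGRecording
from somnifold.preprocess import ArtifactMask

from conftest import FS, phase_randomized

N = int(6 * FS)
T = np.arange(N) / FS


def colored_noise(rng, n, exponent, fs=FS):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(f)
    shape[f > 0] = f[f > 0] ** (-exponent / 2)
    return np.fft.irfft(spec * shape, n)


class TestPSD:
    def test_normalized_psd_sums_to_one(self, rng):
        f, p, tot = compute_psd(rng.standard_normal(N), FS)
        assert p.sum() == pytest.approx(1.0)
        assert tot > 0

    def test_pure_tone_peaks_at_its_frequency(self, rng):
        x = np.sin(2 * np.pi * 10 * T) + 0.05 * rng.standard_normal(N)
        f, p, tot = compute_psd(x, FS)
        feats = spectral_features(f, p, tot)
        assert feats["alpha_peak_freq"] == 10.0

    def test_all_zero_epoch_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_psd(np.zeros(N), FS)

    def test_whitening_flattens_pink_noise(self, rng):
        x = colored_noise(rng, N, 1.0)
        f, p, _ = compute_psd(x, FS)  # whitened
        # raw (unwhitened) spectrum for comparison
        fr, praw = sg.welch(x, fs=FS, nperseg=512)
        lo, hi = (2, 6), (20, 30)

        def ratio(freq, psd):
            return psd[(freq >= lo[0]) & (freq <= lo[1])].mean() \
                / psd[(freq >= hi[0]) & (freq <= hi[1])].mean()

        assert ratio(f, p) < ratio(fr, praw)

    def test_theta_heavy_spectrum_gives_positive_ratios(self, rng):
        x = 4 * colored_noise(rng, N, 0) + 8 * np.sin(2 * np.pi * 6 * T)
        f, p, tot = compute_psd(x, FS)
        feats = spectral_features(f, p, tot)
        assert feats["theta_beta_ratio"] > 0
        assert feats["theta_alpha_ratio"] > 0


class TestSpectralSlope:
    def test_one_over_f2_noise(self, rng):
        vals = [spectral_slope(colored_noise(rng, N, 2.0), FS)
                for _ in range(8)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.3)

    def test_white_noise_is_flat(self, rng):
        vals = [spectral_slope(rng.standard_normal(N), FS) for _ in range(8)]
        assert abs(np.mean(vals)) < 0.2

    def test_monotone_in_steepness(self, rng):
        s1 = np.mean([spectral_slope(colored_noise(rng, N, 1.0), FS)
                      for _ in range(6)])
        s2 = np.mean([spectral_slope(colored_noise(rng, N, 2.5), FS)
                      for _ in range(6)])
        assert s2 > s1


class TestPAC:
    def _coupled(self, rng, depth=1.0):
        theta = sg.sosfiltfilt(sg.butter(4, [5, 7], "bandpass", fs=FS,
                                         output="sos"),
                               rng.standard_normal(N))
        theta /= theta.std()
        phi = np.angle(sg.hilbert(theta))
        beta = sg.sosfiltfilt(sg.butter(4, [15, 25], "bandpass", fs=FS,
                                        output="sos"),
                              rng.standard_normal(N))
        beta /= beta.std()
        amp = 1 + depth * np.cos(phi)
        return theta + amp * beta / 2 + 0.2 * rng.standard_normal(N)

    def test_coupled_exceeds_phase_shuffled_surrogates(self, rng):
        x = self._coupled(rng)
        v = pac(x, (4, 8), (12, 30), FS).value
        surr = [pac(phase_randomized(x, rng), (4, 8), (12, 30), FS).value
                for _ in range(30)]
        assert v > np.percentile(surr, 95)

    def test_independent_noises_give_low_coupling(self, rng):
        vals = [pac(self._coupled(rng, depth=0.0), (4, 8), (12, 30), FS).value
                for _ in range(10)]
        assert np.mean(vals) < 0.2

    def test_value_bounded_and_band_order_enforced(self, rng):
        v = pac(rng.standard_normal(N), (4, 8), (12, 30), FS).value
        assert 0.0 <= v <= 1.0
        with pytest.raises(ValueError):
            pac(rng.standard_normal(N), (8, 12), (4, 8), FS)

    def test_too_short_epoch_gives_nan(self, rng):
        out = pac(rng.standard_normal(32), (1, 4), (12, 30), FS)
        assert np.isnan(out.value)


class TestCoherence:
    def test_stationary_tone_near_unity_in_band(self, rng):
        x = np.sin(2 * np.pi * 10 * T) + 0.01 * rng.standard_normal(N)
        out = temporal_coherence(x, FS)
        # the 10-Hz bin contributes ~1; band sum is at least that
        assert out["alpha_coherence"] > 0.9

    def test_noise_sits_near_floor_and_nonnegative(self, rng):
        tone = temporal_coherence(np.sin(2 * np.pi * 10 * T)
                                  + 0.01 * rng.standard_normal(N), FS)
        noise_vals = [temporal_coherence(rng.standard_normal(N), FS)
                      ["alpha_coherence"] for _ in range(10)]
        assert all(v >= 0 for v in noise_vals)
        assert np.percentile(noise_vals, 95) < tone["alpha_coherence"]


class TestEntropyRate:
    def test_constant_signal_minimal_rate(self):
        out = entropy_rate(np.ones(N))
        assert out.lz <= 2
        assert out.rate <= 2 * np.log2(N) / N

    def test_iid_noise_binarizes_to_fair_coin_rate(self, rng):
        # continuous symmetric noise -> median split is an i.i.d. fair coin
        x = rng.standard_normal(N)
        assert entropy_rate(x).rate == pytest.approx(1.0, abs=0.15)

    def test_sign_symmetric(self, rng):
        x = rng.standard_normal(N)
        assert entropy_rate(x).rate == entropy_rate(-x).rate

    @pytest.mark.parametrize("bits,expected", [
        ("01", 2), ("0001", 2), ("010101010101", 3), ("0110", 3),
    ])
    def test_lz76_known_small_sequences(self, bits, expected):
        arr = np.array([int(b) for b in bits])
        assert lz76_complexity(arr) == expected

    def test_compiled_lz76_matches_reference_scan(self, rng):
        for _ in range(20):
            bits = rng.integers(0, 2, rng.integers(2, 400))
            assert lz76_complexity(bits) == _lz76_reference(bits)


class TestCatch22:
    def test_names_order_and_determinism(self, rng):
        x = rng.standard_normal(N)
        a = catch22_features(x)
        b = catch22_features(x)
        assert list(a) == CATCH22_NAMES
        assert a == b

    def test_constant_series_defined_values(self):
        out = catch22_features(np.full(N, 3.7))
        assert len(out) == 22  # degenerate but no crash

    def test_nonfinite_input_gives_nan_vector(self, rng):
        x = rng.standard_normal(N)
        x[10] = np.nan
        assert all(np.isnan(v) for v in catch22_features(x).values())

    def test_histogram_mode_against_direct_count(self, rng):
        x = rng.standard_normal(400)
        z = (x - x.mean()) / x.std()
        counts, edges = np.histogram(z, bins=5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        expected = centers[np.argmax(counts)]
        assert catch22_features(x)["DN_HistogramMode_5"] == pytest.approx(expected)

    def test_trev_and_pnn40_closed_form(self, rng):
        x = rng.standard_normal(500)
        z = (x - x.mean()) / x.std()
        out = catch22_features(x)
        assert out["CO_trev_1_num"] == pytest.approx(np.mean(np.diff(z) ** 3))
        assert out["MD_hrv_classic_pnn40"] == pytest.approx(
            np.mean(np.abs(np.diff(z)) > 0.04))

    def test_longest_stretch_on_engineered_pattern(self):
        # 30 samples above the mean in one run
        x = np.r_[np.zeros(100), np.ones(30) * 5, np.zeros(100)]
        assert catch22_features(x)["SB_BinaryStats_mean_longstretch1"] == 30

    def test_motif_entropy_of_alternating_sequence(self):
        # strict alternation between two extreme symbols: two equally likely
        # pairs -> entropy ln 2
        x = np.tile([1.0, -1.0], 300)
        out = catch22_features(x)["SB_MotifThree_quantile_hh"]
        assert out == pytest.approx(np.log(2), abs=1e-4)

    def test_ar1_autocorr_features_move_with_dependence(self, rng):
        white = rng.standard_normal(N)
        ar = np.zeros(N)
        for i in range(1, N):
            ar[i] = 0.95 * ar[i - 1] + white[i]
        fw = catch22_features(white)
        fa = catch22_features(ar)
        assert fa["CO_f1ecac"] > fw["CO_f1ecac"]

    def test_compiled_helpers_match_pure_python(self, rng):
        from somnifold.features.catch22 import (_longest_run,
                                                _two_segment_prop_r1,
                                                _outlier_include)
        for _ in range(10):
            bits = rng.integers(0, 2, 200).astype(bool)
            assert _fast.longest_run(bits.astype(np.uint8), np.uint8(1)) \
                == _longest_run(bits, True)
            y = rng.standard_normal(300)
            assert _fast.outlier_mdrmd(y, 0.01) == pytest.approx(
                _outlier_include(y), abs=1e-12)
            lt = np.sort(rng.uniform(0, 3, 20))
            lf = rng.standard_normal(20)
            assert _fast.two_segment_prop_r1(lt, lf) == pytest.approx(
                _two_segment_prop_r1(lt, lf))


class TestFeatureMatrix:
    @pytest.fixture(scope="class")
    def tiny_rec(self):
        rng = np.random.default_rng(77)
        n = int(40 * FS)
        data = rng.normal(0, 10, (2, n))
        return EEGRecording(["C3", "C4"], data, FS)

    def test_feature_set_sizes(self, tiny_rec):
        ft50 = compute_feature_matrix(tiny_rec, feature_set=50)
        ft47 = compute_feature_matrix(tiny_rec, feature_set=47)
        assert ft50.n_features == 50
        assert ft47.n_features == 47
        omitted = set(ft50.feature_names) - set(ft47.feature_names)
        assert omitted == {"sigma_power", "entropy_rate", "spectral_slope"}

    def test_names_unique_and_registry_consistent(self):
        names = feature_names(50)
        assert len(names) == len(set(names)) == 50

    def test_identical_channels_equal_single_channel(self, rng):
        n = int(40 * FS)
        x = rng.normal(0, 10, n)
        one = EEGRecording(["C3"], x[None], FS)
        two = EEGRecording(["C3", "C4"], np.stack([x, x]), FS)
        f1 = compute_feature_matrix(one, feature_set=47)
        f2 = compute_feature_matrix(two, feature_set=47)
        np.testing.assert_allclose(f1.values, f2.values, rtol=1e-10)

    def test_artifact_mask_propagates_as_nan(self, tiny_rec):
        ft = compute_feature_matrix(tiny_rec, feature_set=47)
        mask = np.zeros(ft.n_epochs, dtype=bool)
        mask[3] = True
        masked = compute_feature_matrix(tiny_rec, feature_set=47,
                                        mask=ArtifactMask(mask))
        assert np.all(np.isnan(masked.values[:, 3]))
        other = np.delete(masked.values, 3, axis=1)
        assert np.isfinite(other).all()

    def test_unknown_region_rejected(self, tiny_rec):
        with pytest.raises(ValueError):
            compute_feature_matrix(tiny_rec, region="temporal")
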