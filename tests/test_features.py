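"""Morlet band power, feature layout, transforms, scaling and context."""

import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfiltfilt

from wavesleep.features import (
    BandConfig,
    FeatureLayout,
    add_context,
    band_power_series,
    default_band_table,
    epoch_features,
    extract_recording_features,
    load_band_table,
    morlet_kernel,
    save_band_table,
    scale_per_recording,
    sliding_windows,
    transform_features,
)

FS = 100.0


class TestMorletKernel:
    @pytest.mark.parametrize(
        "freq, cycles, sigma",
        [(10.0, 10, 0.15915), (1.0, 3, 0.47746)],
    )
    def test_gaussian_width_closed_form(self, freq, cycles, sigma):
        assert BandConfig("b", freq, cycles).sigma == pytest.approx(sigma, abs=1e-4)
        kernel = morlet_kernel(freq, cycles, FS)
        # support +/- 4 sigma
        assert len(kernel) == 2 * int(np.ceil(4 * sigma * FS)) + 1

    def test_unit_energy(self):
        for freq, cycles in [(0.5, 3), (10, 10), (40, 5)]:
            k = morlet_kernel(freq, cycles, FS)
            assert np.sum(np.abs(k) ** 2) / FS == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_kernel(50.0, 3, FS)

    def test_kernel_longer_than_signal(self):
        with pytest.raises(ValueError, match="longer segment"):
            band_power_series(np.zeros(100), BandConfig("slow", 0.5, 3), FS)


class TestBandPower:
    def test_zero_signal_gives_zero_power(self):
        bp = band_power_series(np.zeros(3000), BandConfig("a", 10, 10), FS)
        assert bp.shape == (3000,)
        assert np.all(bp == 0)

    def test_pure_tone_envelope_is_flat(self):
        """The analytic amplitude of an on-band tone is constant inside."""
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        bp = band_power_series(x, BandConfig("alpha", 10, 10), FS)
        inner = bp[750:2250]
        assert np.std(inner) / np.mean(inner) < 0.05

    def test_band_selectivity(self):
        """An off-band tone leaks <10% of an on-band tone's power."""
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 1 * t) + np.sin(2 * np.pi * 20 * t)
        p10 = band_power_series(x, BandConfig("a", 10, 10), FS)[750:2250].mean()
        p20 = band_power_series(x, BandConfig("b", 20, 5), FS)[750:2250].mean()
        assert p10 / p20 < 0.1

    def test_matches_narrowband_filter_envelope_oracle(self):
        """Band power of a tone agrees with a filter+Hilbert oracle to 5%."""
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        band = BandConfig("alpha", 10, 10)
        bp = band_power_series(x, band, FS)
        sos = butter(4, [9, 11], btype="bandpass", fs=FS, output="sos")
        env2 = np.abs(hilbert(sosfiltfilt(sos, x))) ** 2
        inner = slice(750, 2250)
        ratio = bp[inner] / env2[inner]
        # both are time-resolved 10 Hz power up to a constant gain
        assert np.std(ratio) / np.mean(ratio) < 0.05


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "epoch, win, step, n",
        [(30, 5, 2.5, 11), (30, 30, 10, 1), (30, 5, 5, 6)],
    )
    def test_window_counts(self, epoch, win, step, n):
        wins = sliding_windows(epoch, win, step)
        assert len(wins) == n
        assert all(b <= epoch for _, b in wins)

    def test_window_longer_than_epoch(self):
        with pytest.raises(ValueError, match="longer"):
            sliding_windows(30, 31, 1)


class TestLayout:
    @pytest.mark.parametrize("n_bands", [3, 22])
    def test_feature_count_formula(self, n_bands):
        layout = FeatureLayout(n_bands=n_bands, n_windows=11)
        expected = n_bands + 11 * n_bands + 1 + 11 + n_bands * (n_bands - 1) // 2 + 50
        assert layout.total == expected
        assert len(layout.column_names()) == expected

    def test_default_configuration_yields_557(self):
        assert len(default_band_table()) == 22
        layout = FeatureLayout(n_bands=22, n_windows=11)
        assert layout.total == 557

    def test_band_table_round_trip(self, tmp_path):
        save_band_table(tmp_path / "bands.txt", default_band_table())
        back = load_band_table(tmp_path / "bands.txt")
        assert back == default_band_table()


class TestEpochFeatures:
    def test_vector_length_and_zero_epoch(self):
        layout = FeatureLayout(n_bands=22, n_windows=11)
        vec = epoch_features(
            np.zeros(3000), np.zeros((22, 3000)), layout, FS
        )
        assert vec.shape == (557,)
        assert np.all(vec == 0)  # powers, degenerate correlations, autocorr

    def test_identical_band_series_correlate_perfectly(self, rng):
        layout = FeatureLayout(n_bands=2, n_windows=11)
        series = rng.random(3000)
        vec = epoch_features(
            rng.random(3000), np.stack([series, series]), layout, FS
        )
        corr = vec[layout.slices()["band_corr"]]
        assert corr[0] == pytest.approx(1.0)

    def test_amplitude_scaling_property(self):
        """Scaling the signal by c scales signal-power blocks by c^2 and
        band-power blocks by c^4 (the band-power series is itself a
        squared magnitude, and its power is a mean of squares), leaving
        correlations and autocorrelations unchanged."""
        rec = np.random.default_rng(0).standard_normal(3000)
        X1, layout = extract_recording_features(rec, FS)
        X2, _ = extract_recording_features(3.0 * rec, FS)
        sl = layout.slices()
        for block in ("epoch_band_power", "window_band_power"):
            np.testing.assert_allclose(X2[:, sl[block]], 81.0 * X1[:, sl[block]],
                                       rtol=1e-9)
        for block in ("epoch_signal_power", "window_signal_power"):
            np.testing.assert_allclose(X2[:, sl[block]], 9.0 * X1[:, sl[block]],
                                       rtol=1e-9)
        for block in ("band_corr", "autocorr"):
            np.testing.assert_allclose(X2[:, sl[block]], X1[:, sl[block]],
                                       rtol=1e-7, atol=1e-12)

    def test_mean_band_power_switch_scales_quadratically(self):
        """The alternative band-power summary (plain mean of the series)
        scales as c^2, matching the signal-power blocks."""
        rec = np.random.default_rng(0).standard_normal(3000)
        X1, layout = extract_recording_features(rec, FS, band_power_stat="mean")
        X2, _ = extract_recording_features(3.0 * rec, FS, band_power_stat="mean")
        sl = layout.slices()
        np.testing.assert_allclose(
            X2[:, sl["epoch_band_power"]], 9.0 * X1[:, sl["epoch_band_power"]],
            rtol=1e-9,
        )

    def test_shift_by_one_epoch_permutes_interior_features(self):
        """Interior epochs of a stationary signal keep their features when
        the signal is translated by a whole epoch."""
        x = np.random.default_rng(1).standard_normal(6 * 3000)
        full, _ = extract_recording_features(x, FS)
        shifted, _ = extract_recording_features(x[3000:], FS)
        # epochs 1..3 of the shifted signal are epochs 2..4 of the original
        np.testing.assert_allclose(shifted[1:4], full[2:5], rtol=1e-6, atol=1e-9)


class TestTransformScaleContext:
    def _layout(self):
        return FeatureLayout(n_bands=2, n_windows=11)

    def test_transform_rules(self):
        layout = self._layout()
        raw = np.zeros((1, layout.total))
        sl = layout.slices()
        raw[0, sl["epoch_band_power"]] = 1.0  # log(1) = 0
        raw[0, sl["autocorr"].start] = -0.5  # squared -> 0.25
        raw[0, sl["band_corr"].start] = 0.3  # unchanged
        out = transform_features(raw, layout)
        assert out[0, sl["epoch_band_power"].start] == 0.0
        assert out[0, sl["autocorr"].start] == 0.25
        assert out[0, sl["band_corr"].start] == 0.3

    def test_negative_power_rejected(self):
        layout = self._layout()
        raw = np.zeros((1, layout.total))
        raw[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative power"):
            transform_features(raw, layout)

    def test_minmax_scaling_per_recording(self):
        col = np.array([[2.0], [4.0], [6.0]])
        out = scale_per_recording(col, np.array(["a", "a", "a"]))
        np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_half(self):
        col = np.array([[3.0], [3.0], [3.0]])
        out = scale_per_recording(col, np.array(["a", "a", "a"]))
        np.testing.assert_allclose(out[:, 0], [0.5, 0.5, 0.5])

    def test_joint_vs_separate_scaling_differ(self):
        col = np.array([[0.0], [1.0], [0.0], [2.0]])
        rids = np.array(["a", "a", "b", "b"])
        separate = scale_per_recording(col, rids)
        joint = scale_per_recording(col, np.array(["a"] * 4))
        assert not np.allclose(separate, joint)

    def test_single_epoch_recording_rejected(self):
        with pytest.raises(ValueError, match="single epoch"):
            scale_per_recording(np.array([[1.0], [2.0]]), np.array(["a", "b"]))

    def test_context_width(self):
        X = np.random.default_rng(0).random((8, 557))
        out = add_context(X, np.array(["a"] * 8), width=2)
        assert out.shape == (8, 2785)

    def test_single_epoch_recording_replicates(self):
        X = np.array([[1.0, 2.0]])
        out = add_context(X, np.array(["a"]), width=2)
        np.testing.assert_array_equal(out, [[1, 2] * 5])

    def test_context_does_not_cross_recordings(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        rids = np.array(["a"] * 3 + ["b"] * 3)
        out = add_context(X, rids, width=2)
        assert np.all(out[:3] == 0)
        assert np.all(out[3:] == 1)

    def test_non_contiguous_recordings_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="contiguous"):
            add_context(X, np.array(["a", "b", "a"]), width=1)
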