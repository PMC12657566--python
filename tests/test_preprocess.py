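"""Preprocessing chain: OD, TDDR, SSR, SCI, interpolation, MBLL, filter."""

import numpy as np
import pytest
from scipy import signal

from nirsconn.errors import ConfigurationError, DataError, StateError
from nirsconn.montage import Montage, frontal_montage
from nirsconn.preprocess import (
    BeerLambertConfig,
    bandpass,
    design_bandpass,
    flag_bad_channels,
    hemo_to_od,
    intensity_to_od,
    interpolate_bad_channels,
    negative_correlation_enhance,
    od_to_hemo,
    preprocess_recording,
    scalp_coupling_index,
    short_channel_regress,
    tddr,
    tddr_recording,
)
from nirsconn.recording import HemoRecording, OpticalRecording
from nirsconn.synth import SimulationConfig, simulate_hemo, simulate_optical


def _recording(intensities, fs=5.1, n_short=0, stage="intensity"):
    n_ch = intensities.shape[1]
    rng = np.random.default_rng(0)
    src = rng.normal(size=(n_ch, 3)) + [0, 9, 0]
    det = src + [3.5, 0, 0]
    channels = [(i, i) for i in range(n_ch)]
    for k in range(n_short):
        det[n_ch - 1 - k] = src[n_ch - 1 - k] + [0.76, 0, 0]
    return OpticalRecording(
        intensities=intensities, sampling_rate=fs,
        montage=Montage(src, det, channels), stage=stage,
    )


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        rec = _recording(np.full((100, 2, 2), 3.7))
        od = intensity_to_od(rec)
        assert np.allclose(od.intensities, 0.0)
        assert od.stage == "od"

    def test_decade_drop_gives_unit_od(self):
        x = np.ones((100, 1, 2))
        x[50, 0, :] = 0.1  # one sample at I/10 of an (almost) constant series
        rec = _recording(x)
        od = intensity_to_od(rec)
        base = -np.log10(x / x.mean(axis=0))
        assert np.allclose(od.intensities, base)

    def test_od_is_invertible(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(0, 0.1, (200, 3, 2)))
        rec = _recording(x)
        od = intensity_to_od(rec)
        back = 10.0 ** (-od.intensities) * x.mean(axis=0, keepdims=True)
        assert np.allclose(back, x, rtol=1e-12)

    def test_non_positive_intensity_rejected(self):
        x = np.ones((50, 2, 2))
        x[10, 1, 0] = 0.0
        with pytest.raises(DataError, match="channel 1"):
            _recording(x)


class TestTDDR:
    def test_constant_series_unchanged(self):
        x = np.full(200, 2.5)
        assert np.allclose(tddr(x, 5.1), x)

    def test_motion_bump_amplitude_reduced(self):
        # a 20-SD slow motion bump (5 s) is attenuated by >= 80%
        rng = np.random.default_rng(2)
        x = 0.05 * rng.standard_normal(1530)
        w = int(5 * 5.1)
        spike = np.zeros_like(x)
        spike[700 : 700 + w] = 20 * x.std() * np.sin(np.pi * np.arange(w) / w)
        y = tddr(x + spike, 5.1)
        residual_peak = np.abs(y - x)[680 : 700 + w + 20].max()
        assert residual_peak <= 0.2 * spike.max()

    def test_clean_noisy_signal_preserved(self):
        # in its operating regime (derivative dominated by instrument
        # noise) TDDR leaves the series nearly unchanged
        rng = np.random.default_rng(3)
        t = np.arange(0, 300, 1 / 5.1)
        x = np.sin(2 * np.pi * 0.05 * t) + 0.05 * rng.standard_normal(t.size)
        y = tddr(x, 5.1)
        assert np.corrcoef(y, x)[0, 1] > 0.99

    def test_non_finite_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(DataError):
            tddr(x, 5.1)

    def test_preserves_length(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(517)
        assert tddr(x, 5.1).shape == x.shape


class TestShortChannelRegression:
    def test_identical_series_gives_zero_residual(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(300)
        x = np.zeros((300, 2, 2))
        x[:, 0, :] = s[:, None]
        x[:, 1, :] = s[:, None]
        rec = _recording(x, n_short=1, stage="od")
        out = short_channel_regress(rec)
        assert np.allclose(out.intensities[:, 0, :], 0.0, atol=1e-10)

    def test_orthogonal_series_unchanged(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(400)
        s = rng.standard_normal(400)
        for v in (y, s):
            v -= v.mean()
        y -= (y @ s) / (s @ s) * s  # exactly orthogonal, zero-mean
        x = np.zeros((400, 2, 2))
        x[:, 0, :] = y[:, None]
        x[:, 1, :] = s[:, None]
        rec = _recording(x, n_short=1, stage="od")
        out = short_channel_regress(rec)
        assert np.allclose(out.intensities[:, 0, :], y[:, None], atol=1e-10)

    def test_residual_orthogonal_to_regressor(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((500, 3, 2))
        rec = _recording(x, n_short=1, stage="od")
        out = short_channel_regress(rec)
        for c in (0, 1):
            for w in (0, 1):
                res = out.intensities[:, c, w]
                reg = x[:, 2, w]
                assert abs(res @ reg) / (np.linalg.norm(res) * np.linalg.norm(reg)) < 1e-8

    def test_known_superficial_mixing_removed(self):
        cfg = SimulationConfig(
            duration=300, n_long_channels=12, n_short_channels=4, seed=8,
            artifact_rate=0,
        )
        from nirsconn.synth import simulate_cluster_network

        net = simulate_cluster_network(12, 3, seed=1)
        hemo = simulate_hemo(net, cfg)
        rec, truth = simulate_optical(hemo, cfg, return_truth=True)
        od = short_channel_regress(intensity_to_od(rec))
        long_ix = rec.montage.long_indices()
        sup = truth["superficial"]
        cors = [
            abs(np.corrcoef(od.intensities[:, c, 0], sup[:, truth["region_of_long"][i]])[0, 1])
            for i, c in enumerate(long_ix)
        ]
        assert np.mean(cors) < 0.1

    def test_no_short_channels_rejected(self):
        rec = _recording(np.ones((100, 2, 2)) + 0.1, stage="od")
        with pytest.raises(ConfigurationError):
            short_channel_regress(rec)


class TestScalpCouplingIndex:
    def _cardiac_recording(self, shared=True, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 300, 1 / 5.1)
        x = np.zeros((t.size, 2, 2))
        for c in range(2):
            card = np.sin(2 * np.pi * 1.1 * t + rng.uniform(0, 6))
            for w in range(2):
                sig = card if shared else rng.standard_normal(t.size)
                x[:, c, w] = sig + 0.0 * rng.standard_normal(t.size)
        return _recording(x, stage="od")

    def test_shared_cardiac_gives_unit_sci(self):
        rec = self._cardiac_recording(shared=True)
        sci = scalp_coupling_index(rec)
        assert np.all(sci > 0.999)

    def test_independent_noise_gives_low_sci(self):
        rec = self._cardiac_recording(shared=False, seed=1)
        sci = scalp_coupling_index(rec)
        assert np.all(np.abs(sci) < 0.3)

    def test_threshold_is_strict_inequality(self):
        sci = np.array([0.69, 0.70, 0.71, np.nan])
        bad = flag_bad_channels(sci, 0.7)
        assert bad == {0, 3}

    def test_too_short_recording_rejected(self):
        rec = _recording(np.ones((30, 2, 2)) + 0.1, stage="od")
        with pytest.raises(DataError):
            scalp_coupling_index(rec)


class TestInterpolation:
    def test_identical_field_reconstructed(self):
        mont = frontal_montage(12, 0, seed=0)
        rng = np.random.default_rng(9)
        s = rng.standard_normal(200)
        x = np.tile(s[:, None, None], (1, 12, 2))
        rec = OpticalRecording(x, 5.1, mont, stage="od")
        out = interpolate_bad_channels(rec, {3})
        err = out.intensities[:, 3, 0] - s
        assert np.sqrt((err**2).mean()) < 0.01 * s.std()

    def test_empty_bad_set_is_identity(self):
        mont = frontal_montage(8, 0, seed=0)
        x = np.random.default_rng(10).standard_normal((100, 8, 2))
        rec = OpticalRecording(x, 5.1, mont, stage="od")
        out = interpolate_bad_channels(rec, set())
        assert np.array_equal(out.intensities, x)

    def test_smooth_gradient_beats_nearest_neighbour(self):
        mont = frontal_montage(20, 0, seed=1)
        pos = mont.midpoints
        rng = np.random.default_rng(11)
        temporal = rng.standard_normal(150)
        # field varying smoothly left to right across the montage
        gains = 1.0 + 0.5 * (pos[:, 0] - pos[:, 0].min()) / np.ptp(pos[:, 0])
        x = temporal[:, None, None] * gains[None, :, None] * np.ones((1, 1, 2))
        rec = OpticalRecording(x, 5.1, mont, stage="od")
        bad = 7
        out = interpolate_bad_channels(rec, {bad})
        spline_err = np.abs(out.intensities[:, bad, 0] - x[:, bad, 0]).mean()
        others = [i for i in range(20) if i != bad]
        nn = others[
            int(np.argmin(np.linalg.norm(pos[others] - pos[bad], axis=1)))
        ]
        nn_err = np.abs(x[:, nn, 0] - x[:, bad, 0]).mean()
        assert spline_err < nn_err

    def test_too_few_good_channels_rejected(self):
        mont = frontal_montage(4, 0, seed=0)
        x = np.random.default_rng(0).standard_normal((50, 4, 2))
        rec = OpticalRecording(x, 5.1, mont, stage="od")
        with pytest.raises(DataError):
            interpolate_bad_channels(rec, {0, 1})


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        mont = frontal_montage(4, 2, seed=0)
        rec = OpticalRecording(np.zeros((50, 6, 2)), 5.1, mont, stage="od")
        hemo = od_to_hemo(rec)
        assert np.allclose(hemo.hbo, 0) and np.allclose(hemo.hbr, 0)

    def test_forward_inverse_round_trip(self):
        mont = frontal_montage(5, 2, seed=0)
        rng = np.random.default_rng(12)
        hbo = rng.normal(0, 0.5, (80, 7))
        hbr = rng.normal(0, 0.2, (80, 7))
        blc = BeerLambertConfig()
        od = hemo_to_od(hbo, hbr, mont.separations, blc)
        rec = OpticalRecording(od, 5.1, mont, stage="od")
        out = od_to_hemo(rec, blc)
        long_ix = mont.long_indices()
        assert np.allclose(out.hbo, hbo[:, long_ix], atol=1e-9)
        assert np.allclose(out.hbr, hbr[:, long_ix], atol=1e-9)

    def test_doubling_ppf_halves_concentrations(self):
        mont = frontal_montage(4, 0, seed=0)
        rng = np.random.default_rng(13)
        od = rng.normal(0, 0.01, (60, 4, 2))
        rec = OpticalRecording(od, 5.1, mont, stage="od")
        a = od_to_hemo(rec, BeerLambertConfig(ppf=(6.0, 6.0)))
        b = od_to_hemo(rec, BeerLambertConfig(ppf=(12.0, 12.0)))
        assert np.allclose(b.hbo, 0.5 * a.hbo)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ConfigurationError):
            BeerLambertConfig(extinction=np.ones((2, 2)))


class TestEnhancement:
    def _hemo(self, hbo, hbr):
        return HemoRecording(hbo=hbo, hbr=hbr, sampling_rate=5.1, stage="hemo")

    def test_enforces_perfect_anticorrelation(self):
        rng = np.random.default_rng(14)
        hemo = self._hemo(rng.standard_normal((300, 4)), rng.standard_normal((300, 4)))
        out = negative_correlation_enhance(hemo)
        for c in range(4):
            r = np.corrcoef(out.hbo[:, c], out.hbr[:, c])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-6)

    def test_already_anticorrelated_shape_preserved(self):
        rng = np.random.default_rng(15)
        hbo = rng.standard_normal((200, 1))
        hemo = self._hemo(hbo, -0.4 * hbo)
        out = negative_correlation_enhance(hemo)
        assert abs(np.corrcoef(out.hbo[:, 0], hbo[:, 0])[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_variance_not_inflated_by_independent_noise(self):
        rng = np.random.default_rng(16)
        hemo = self._hemo(rng.standard_normal((500, 2)), rng.standard_normal((500, 2)))
        out = negative_correlation_enhance(hemo)
        assert np.all(out.hbo.var(axis=0) <= hemo.hbo.var(axis=0))


class TestBandpass:
    def _tone(self, freq, duration=600.0, fs=5.1):
        t = np.arange(0, duration, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        return HemoRecording(
            hbo=x[:, None], hbr=-x[:, None], sampling_rate=fs, stage="hemo"
        )

    def test_passband_tone_preserved(self):
        out = bandpass(self._tone(0.05))
        mid = slice(500, -500)
        ratio = out.hbo[mid, 0].std() / self._tone(0.05).hbo[mid, 0].std()
        assert 0.9 < ratio < 1.1

    def test_cardiac_tone_suppressed(self):
        out = bandpass(self._tone(1.2))
        mid = slice(800, -800)
        ratio = out.hbo[mid, 0].std() / self._tone(1.2).hbo[mid, 0].std()
        assert ratio < 0.1

    def test_dc_removed(self):
        hemo = self._tone(0.05)
        hemo.hbo += 5.0
        out = bandpass(hemo)
        assert abs(out.hbo.mean()) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        hemo = self._tone(0.05, fs=0.3)
        with pytest.raises(ConfigurationError):
            bandpass(hemo)

    def test_taps_capped_below_signal_length(self):
        taps = design_bandpass(5.1, 400)
        assert len(taps) < 400


class TestChainContract:
    def test_out_of_order_calls_rejected(self, small_network, small_config):
        hemo = simulate_hemo(small_network, small_config)
        rec = simulate_optical(hemo, small_config)
        with pytest.raises(StateError):
            tddr_recording(rec)  # TDDR before OD conversion
        od = intensity_to_od(rec)
        with pytest.raises(StateError):
            intensity_to_od(od)  # OD twice
        odr = tddr_recording(od)
        with pytest.raises(StateError):
            tddr_recording(odr)  # TDDR twice
        h = od_to_hemo(short_channel_regress(odr))
        filtered = bandpass(negative_correlation_enhance(h))
        with pytest.raises(StateError):
            negative_correlation_enhance(filtered)  # enhancement after filter

    def test_no_stage_changes_sample_count(self, small_network, small_config):
        hemo = simulate_hemo(small_network, small_config)
        rec = simulate_optical(hemo, small_config)
        n = rec.n_times
        out, _ = preprocess_recording(rec)
        assert out.n_times == n

    def test_end_to_end_recovers_band_limited_signal(self, small_network):
        # artifact-free data: the chain must preserve the cortical HbO
        # signal; with motion repair skipped (nothing to repair) the
        # band-limited ground truth is recovered almost exactly, and the
        # robust repair itself costs a bounded amount of fidelity
        cfg = SimulationConfig(
            duration=300, n_long_channels=12, n_short_channels=4, seed=21,
            artifact_rate=0,
        )
        hemo = simulate_hemo(small_network, cfg)
        rec = simulate_optical(hemo, cfg)
        taps = design_bandpass(cfg.sampling_rate, hemo.n_times)
        truth = signal.filtfilt(
            taps, 1.0, hemo.hbo, axis=0, padlen=min(3 * len(taps), hemo.n_times - 1)
        )

        out, _ = preprocess_recording(rec, apply_tddr=False)
        good = [i for i in range(12) if i not in out.bad_channels]
        cors = [np.corrcoef(out.hbo[:, i], truth[:, i])[0, 1] for i in good]
        assert np.mean(cors) > 0.95

        out2, _ = preprocess_recording(rec, apply_tddr=True)
        good2 = [i for i in range(12) if i not in out2.bad_channels]
        cors2 = [np.corrcoef(out2.hbo[:, i], truth[:, i])[0, 1] for i in good2]
        assert np.mean(cors2) > 0.7
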