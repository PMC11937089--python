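"""Filtering, bad channels, referencing, virtual channels and ASR."""

import numpy as np
import pytest

from drivevigil.eeg_clean import (asr_apply, asr_fit, clean_merged,
                                  derive_virtual_channels,
                                  detect_bad_channels, fir_bandpass,
                                  interpolate_bad_channels, reref_mastoids)
from drivevigil.montage import (CAP_LABELS, GRID_LABELS, VirtualChannelMap,
                                default_virtual_map)
from drivevigil.streams import ChannelTimeSeries

FS = 250.0


def sine(freq, dur=60.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def series(data, labels=None):
    data = np.atleast_2d(data)
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return ChannelTimeSeries(data, labels, FS)


class TestFirBandpass:
    def test_dc_removed(self):
        out = fir_bandpass(series(np.ones(int(60 * FS))), 1.0, 40.0)
        assert np.abs(out.data[0, 2000:-2000]).max() < 0.01

    def test_passband_gain(self):
        out = fir_bandpass(series(sine(10.0)), 1.0, 40.0)
        amp = np.abs(out.data[0, 2000:-2000]).max()
        assert 0.95 <= amp <= 1.05

    def test_stopband_attenuation(self):
        out = fir_bandpass(series(sine(50.0)), 1.0, 40.0)
        assert np.abs(out.data[0, 2000:-2000]).max() < 0.1

    def test_high_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_bandpass(series(sine(10.0)), 1.0, 130.0)

    def test_linearity_preserves_frequency(self):
        out = fir_bandpass(series(sine(10.0, amp=2.0)), 0.1, 40.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        f = np.fft.rfftfreq(out.n_samples, 1 / FS)
        assert abs(f[np.argmax(spec)] - 10.0) < 0.1


class TestBadChannels:
    def _noise(self, rng, n_ch=8, flat=None, noisy=None):
        base = rng.standard_normal((1, int(70 * FS)))
        data = np.vstack([0.6 * base + rng.standard_normal(base.shape)
                          for _ in range(n_ch)])
        if flat is not None:
            data[flat] = 0.0
        if noisy is not None:
            data[noisy] *= 50.0
        return series(data)

    def test_comparable_channels_pass(self, rng):
        iid = series(rng.standard_normal((8, int(70 * FS))))
        assert detect_bad_channels(iid) == set()

    def test_zeroed_channel_flagged_flat(self, rng):
        assert "ch2" in detect_bad_channels(self._noise(rng, flat=2))

    def test_amplified_channel_flagged_noisy(self, rng):
        assert "ch3" in detect_bad_channels(self._noise(rng, noisy=3))

    def test_short_data_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_bad_channels(series(rng.standard_normal((3, 100))))


class TestInterpolation:
    def _cap(self, rng):
        data = rng.standard_normal((len(CAP_LABELS), 1000))
        return ChannelTimeSeries(data, CAP_LABELS, FS)

    def test_empty_bads_identity(self, rng):
        s = self._cap(rng)
        np.testing.assert_array_equal(
            interpolate_bad_channels(s, set()).data, s.data)

    def test_identical_neighbors_reconstructed_exactly(self, rng):
        s = self._cap(rng)
        common = rng.standard_normal(1000)
        for lab in CAP_LABELS:
            if lab != "P4":
                s.data[CAP_LABELS.index(lab)] = common
        out = interpolate_bad_channels(s, {"P4"})
        np.testing.assert_allclose(out.data[CAP_LABELS.index("P4")], common)

    def test_grid_channel_rejected(self, rng):
        data = rng.standard_normal((len(GRID_LABELS), 1000))
        g = ChannelTimeSeries(data, GRID_LABELS, FS)
        with pytest.raises(ValueError):
            interpolate_bad_channels(g, {"G_P"}, positions={})


class TestReref:
    def test_arithmetic(self):
        data = np.zeros((len(CAP_LABELS), 4))
        data[CAP_LABELS.index("Cz")] = 5.0
        data[CAP_LABELS.index("M1")] = 2.0
        data[CAP_LABELS.index("M2")] = 4.0
        out = reref_mastoids(ChannelTimeSeries(data, CAP_LABELS, FS))
        np.testing.assert_allclose(out.data[CAP_LABELS.index("Cz")], 2.0)

    def test_zero_mastoids_identity(self, rng):
        data = rng.standard_normal((len(CAP_LABELS), 100))
        data[CAP_LABELS.index("M1")] = 0.0
        data[CAP_LABELS.index("M2")] = 0.0
        out = reref_mastoids(ChannelTimeSeries(data, CAP_LABELS, FS))
        np.testing.assert_allclose(out.data, data)

    def test_double_application_refused(self, rng):
        s = ChannelTimeSeries(rng.standard_normal((len(CAP_LABELS), 100)),
                              CAP_LABELS, FS)
        once = reref_mastoids(s)
        with pytest.raises(ValueError):
            reref_mastoids(once)

    def test_missing_mastoid_rejected(self, rng):
        s = series(rng.standard_normal((2, 100)), ["Cz", "Pz"])
        with pytest.raises(KeyError):
            reref_mastoids(s)


class TestVirtualChannels:
    def test_linear_combination_value(self):
        data = np.zeros((len(GRID_LABELS), 3))
        data[GRID_LABELS.index("G_FP")] = 3e-6
        data[GRID_LABELS.index("G_M2")] = 1e-6
        g = ChannelTimeSeries(data, GRID_LABELS, FS)
        out = derive_virtual_channels(g)
        np.testing.assert_allclose(out.data[out.labels.index("FPz_M2")],
                                   2e-6)

    def test_zero_in_zero_out(self):
        g = ChannelTimeSeries(np.zeros((len(GRID_LABELS), 5)), GRID_LABELS,
                              FS)
        assert np.all(derive_virtual_channels(g).data == 0.0)

    def test_linearity(self, rng):
        a = ChannelTimeSeries(rng.standard_normal((len(GRID_LABELS), 50)),
                              GRID_LABELS, FS)
        b = ChannelTimeSeries(rng.standard_normal((len(GRID_LABELS), 50)),
                              GRID_LABELS, FS)
        ab = ChannelTimeSeries(a.data + b.data, GRID_LABELS, FS)
        np.testing.assert_allclose(
            derive_virtual_channels(ab).data,
            derive_virtual_channels(a).data + derive_virtual_channels(b).data,
            atol=1e-12)

    def test_missing_source_named_in_error(self):
        vmap = VirtualChannelMap(combos={"X": [("NOPE", 1.0),
                                               ("G_M2", -1.0)]})
        g = ChannelTimeSeries(np.zeros((len(GRID_LABELS), 5)), GRID_LABELS,
                              FS)
        with pytest.raises(KeyError, match="NOPE"):
            vmap.apply(g)

    def test_single_source_map_rejected(self):
        with pytest.raises(ValueError):
            VirtualChannelMap(combos={"X": [("G_FP", 1.0)]})

    def test_commutes_with_filtering(self, rng):
        g = ChannelTimeSeries(
            1e-6 * rng.standard_normal((len(GRID_LABELS), int(70 * FS))),
            GRID_LABELS, FS)
        a = derive_virtual_channels(fir_bandpass(g, 1.0, 40.0))
        b = fir_bandpass(derive_virtual_channels(g), 1.0, 40.0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)


class TestASR:
    def _clean(self, rng, n_ch=6, dur=120.0):
        data = 5e-6 * rng.standard_normal((n_ch, int(dur * FS)))
        shared = 5e-6 * rng.standard_normal(int(dur * FS))
        return series(data + shared)

    def test_clean_data_passes_through(self, rng):
        s = self._clean(rng)
        model = asr_fit(s)
        out = asr_apply(s, model)
        change = np.sqrt(np.mean((out.data - s.data) ** 2)) / \
            np.sqrt(np.mean(s.data ** 2))
        assert change < 0.05

    def test_burst_removed_neighbors_untouched(self, rng):
        s = self._clean(rng)
        model = asr_fit(s)
        burst = s.copy()
        i0, i1 = int(60.0 * FS), int(60.3 * FS)
        t = np.arange(i1 - i0) / FS
        burst.data[:, i0:i1] += 500e-6 * np.sin(2 * np.pi * 5 * t) * \
            np.hanning(i1 - i0)
        out = asr_apply(burst, model)
        rms_before = np.sqrt(np.mean(burst.data[:, i0:i1] ** 2))
        rms_after = np.sqrt(np.mean(out.data[:, i0:i1] ** 2))
        assert rms_after <= 0.2 * rms_before
        j0, j1 = int(55.0 * FS), int(58.0 * FS)
        neigh_change = np.sqrt(np.mean(
            (out.data[:, j0:j1] - burst.data[:, j0:j1]) ** 2)) / \
            np.sqrt(np.mean(burst.data[:, j0:j1] ** 2))
        assert neigh_change < 0.05

    def test_infinite_cutoff_identity(self, rng):
        s = self._clean(rng)
        model = asr_fit(s, cutoff_k=1e12)
        out = asr_apply(s, model)
        np.testing.assert_allclose(out.data, s.data, rtol=1e-6, atol=1e-12)

    def test_rank_deficient_calibration_rejected(self, rng):
        x = 5e-6 * rng.standard_normal((3, int(90 * FS)))
        dup = np.vstack([x, x[0]])   # exact duplicate channel
        with pytest.raises(ValueError, match="rank"):
            asr_fit(series(dup))

    def test_short_calibration_rejected(self, rng):
        with pytest.raises(ValueError):
            asr_fit(self._clean(rng, dur=30.0))

    def test_channel_set_mismatch_rejected(self, rng):
        s = self._clean(rng)
        model = asr_fit(s)
        other = self._clean(rng, n_ch=4)
        with pytest.raises(ValueError):
            asr_apply(other, model)


def test_sine_survives_full_chain(rng):
    """Linear-phase chain: a pure 10 Hz alpha-like sine keeps its frequency
    and amplitude (within 5 %) through bandpass + ASR."""
    n = int(120 * FS)
    t = np.arange(n) / FS
    target = 10e-6 * np.sin(2 * np.pi * 10 * t)
    data = 3e-6 * np.random.default_rng(0).standard_normal((6, n))
    data[2] += target
    s = series(data)
    cleaned = clean_merged(s)
    seg = slice(int(10 * FS), int(110 * FS))
    corr = np.corrcoef(cleaned.data[2, seg], target[seg])[0, 1]
    assert corr > 0.9
    amp_in = np.sqrt(2 * np.mean(target[seg] ** 2))
    resid = cleaned.data[2, seg] - np.mean(cleaned.data[2, seg])
    proj = 2 * np.mean(resid * np.sin(2 * np.pi * 10 * t[seg]))
    assert abs(proj - 10e-6) / 10e-6 < 0.05
    assert amp_in == pytest.approx(10e-6, rel=0.01)
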