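"""Signal-level generators: lateral dynamics, EEG, eyes, ECG."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from drivevigil.streams import Event, EventList
from drivevigil.synth import (EffectConfig, ScenarioConfig,
                              plan_eye_schedule, simulate_lateral_dynamics,
                              synthesize_ecg, synthesize_eeg,
                              synthesize_eyes)
from drivevigil.synth.eeg import (BACKGROUND_DB_AT_10HZ,
                                  background_band_mean)
from drivevigil.peripheral import detect_rpeaks


def scenario(**kw):
    kw.setdefault("duration_s", 360.0)
    kw.setdefault("section_s", 60.0)
    return ScenarioConfig(**kw)


class TestLateralDynamics:
    def test_pad_holds_lane_without_gusts(self, rng):
        telem, crashes = simulate_lateral_dynamics(
            EventList([]), "PAD", scenario(), rng)
        assert np.abs(telem.data[0]).max() < 0.05
        assert len(crashes) == 0

    def test_pad_residual_small_under_gusts(self, rng):
        gusts = EventList([Event(30.0 * i + 10, "gust",
                                 {"direction": (-1) ** i, "speed_kmh": 30.0})
                           for i in range(10)])
        telem, _ = simulate_lateral_dynamics(gusts, "PAD", scenario(), rng)
        assert np.abs(telem.data[0]).max() < 0.05

    def test_uncorrected_gust_moves_over_a_meter(self, rng):
        gusts = EventList([Event(10.0, "gust",
                                 {"direction": 1, "speed_kmh": 30.0})])
        telem, _ = simulate_lateral_dynamics(gusts, "Manual", scenario(), rng,
                                             driver_gain=0.0)
        assert np.abs(telem.data[0]).max() > 1.0

    def test_crash_resets_to_lane_center(self, rng):
        gusts = EventList([Event(10.0, "gust",
                                 {"direction": 1, "speed_kmh": 30.0})])
        telem, crashes = simulate_lateral_dynamics(
            gusts, "Manual", scenario(duration_s=60, section_s=10), rng,
            driver_gain=0.0)
        assert len(crashes) >= 1
        i = int(crashes[0].time * 10)
        assert telem.data[0, i] == 0.0

    def test_manual_rmse_grows_in_expectation(self):
        """Injected steering-noise growth: section RMSE averaged over 20
        seeds is non-decreasing."""
        sc = scenario()
        eff = EffectConfig()
        acc = np.zeros(6)
        from drivevigil.synth.scenario import generate_gust_events
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gusts = generate_gust_events(sc, rng)
            telem, _ = simulate_lateral_dynamics(gusts, "Manual", sc, rng,
                                                 eff)
            x, t = telem.data[0], telem.times()
            for s in range(6):
                acc[s] += np.sqrt(np.mean(x[(t >= s * 60) &
                                            (t < (s + 1) * 60)] ** 2))
        acc /= 20
        assert np.all(np.diff(acc) > -0.01)
        assert acc[5] > acc[0]

    def test_distance_monotone_velocity_constant(self, rng):
        telem, _ = simulate_lateral_dynamics(EventList([]), "Manual",
                                             scenario(), rng)
        d = telem.data[telem.labels.index("distance_m")]
        assert np.all(np.diff(d) >= 0)
        v = telem.data[telem.labels.index("velocity_kmh")]
        assert np.all(v == 80.0)


class TestSynthesizeEEG:
    def test_background_only_matches_one_over_f_model(self, rng):
        """With oscillator amplitudes effectively zero the alpha-band mean
        PSD equals the analytic 1/f background within 1 dB."""
        eff = EffectConfig(band_base_db={"alpha": -160.0, "beta": -160.0,
                                         "theta": -160.0},
                           band_mode_delta_db={"alpha": 0, "beta": 0,
                                               "theta": 0},
                           band_time_profile_db={b: [0.0] * 6 for b in
                                                 ("alpha", "beta", "theta")},
                           band_cell_noise_db=0.0,
                           artifact_rate_per_hour=0.0,
                           dropout_rate_per_hour=0.0)
        cap, _, _, _, _ = synthesize_eeg(eff, scenario(), "Manual", rng,
                                         blink_times=np.array([]))
        # remove the mastoid common mode, as the analysis reference does
        ref = 0.5 * (cap.data[cap.labels.index("M1")] +
                     cap.data[cap.labels.index("M2")])
        f, p = signal.welch(cap.data[cap.labels.index("P4")] - ref, fs=250.0,
                            nperseg=2048)
        band = (f >= 8) & (f <= 12)
        measured_db = 10 * np.log10(p[band].mean())
        model_db = 10 * np.log10(background_band_mean((8.0, 12.0)))
        assert abs(measured_db - model_db) < 1.0

    def test_time_profile_configuration_echo(self):
        eff = EffectConfig()
        prof = dict(eff.band_time_profile_db)
        prof["alpha"] = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        eff2 = dataclasses.replace(eff, band_time_profile_db=prof)
        t = eff2.band_targets_db("alpha", "Manual")
        assert t[5] - t[0] == pytest.approx(1.0)

    def test_mode_delta_recovered_from_raw_grid(self):
        """PAD-minus-Manual alpha at the virtual parietal channel recovers
        the injected +1.24 dB within 0.3 dB, averaged over seeds."""
        eff = EffectConfig(artifact_rate_per_hour=0.0,
                           dropout_rate_per_hour=0.0)
        sc = scenario()
        deltas = []
        for seed in range(8):
            psds = {}
            for cond in ("PAD", "Manual"):
                rng = np.random.default_rng(seed)
                _, grid, _, _, _ = synthesize_eeg(eff, sc, cond, rng,
                                                  blink_times=np.array([]))
                virt = grid.data[grid.labels.index("G_P")] - \
                    grid.data[grid.labels.index("G_M2")]
                f, p = signal.welch(virt, fs=250.0, nperseg=2048)
                band = (f >= 8) & (f <= 12)
                psds[cond] = 10 * np.log10(p[band].mean())
            deltas.append(psds["PAD"] - psds["Manual"])
        assert np.mean(deltas) == pytest.approx(1.24, abs=0.3)

    def test_dropouts_zero_data_and_are_logged(self):
        eff = EffectConfig(dropout_rate_per_hour=200.0,
                           artifact_rate_per_hour=0.0)
        rng = np.random.default_rng(3)
        cap, _, _, _, dropouts = synthesize_eeg(eff, scenario(), "Manual",
                                                rng,
                                                blink_times=np.array([]))
        assert len(dropouts) > 0
        t0, t1 = dropouts[0]
        seg = cap.data[:, int(t0 * 250) + 1: int(t1 * 250) - 1]
        assert np.all(seg == 0.0)


class TestEyes:
    def test_fully_open_without_closure(self, rng):
        eff = EffectConfig(perclos_base=0.0, perclos_mode_delta=0.0,
                           perclos_time_profile=[0.0] * 6,
                           blink_rate_per_min=0.0,
                           eye_invalid_fraction=0.0)
        sc = scenario()
        sch = plan_eye_schedule(eff, sc, "Manual", rng)
        eyes = synthesize_eyes(eff, sc, sch, rng)
        op = eyes.data[eyes.labels.index("left_openness")]
        assert op.min() > 0.99 * 10.0

    def test_duty_cycle_recovers_target(self, rng):
        """A constant 10 % closure target is recovered within 1 %
        absolute from the generated openness stream."""
        eff = EffectConfig(perclos_base=0.10, perclos_mode_delta=0.0,
                           perclos_time_profile=[0.0] * 6,
                           eye_invalid_fraction=0.0)
        sc = scenario()
        sch = plan_eye_schedule(eff, sc, "Manual", rng)
        eyes = synthesize_eyes(eff, sc, sch, rng)
        op = eyes.data[eyes.labels.index("left_openness")]
        closure = 1.0 - op / 10.0
        assert closure.mean() == pytest.approx(0.10, abs=0.01)


class TestECG:
    def test_beat_count(self, rng):
        eff = EffectConfig(heart_rate_bpm=72.0, sdrr_base_ms=5.0,
                           sdrr_time_profile_ms=[0.0] * 6)
        sc = scenario(duration_s=60.0, section_s=10.0)
        ecg, _, peaks = synthesize_ecg(eff, sc, "Manual", rng)
        assert abs(len(peaks) - 72) <= 2
        rr = detect_rpeaks(ecg, prominence=0.5)
        assert abs(len(rr.peak_times) - len(peaks)) <= 1

    def test_sdrr_recovered(self, rng):
        eff = EffectConfig(heart_rate_bpm=60.0, sdrr_base_ms=20.0,
                           sdrr_time_profile_ms=[0.0] * 6)
        sc = scenario()
        ecg, _, _ = synthesize_ecg(eff, sc, "Manual", rng)
        rr = detect_rpeaks(ecg, prominence=0.5)
        first_min = rr.rr_ms[rr.peak_times[1:] < 60.0]
        assert np.std(first_min, ddof=1) == pytest.approx(20.0, abs=5.0)
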