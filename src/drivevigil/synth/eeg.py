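"""Synthetic EEG for the cap and the around-ear grid.

Signal model: each channel carries a 1/f background (half shared across
channels, half channel-specific) plus band-limited Gaussian oscillations
in the theta (4-8 Hz), alpha (8-12 Hz) and beta (13-26 Hz) bands whose
section-wise band-mean PSD hits the configured dB targets exactly (the
flat in-band oscillator PSD is solved from target minus analytic
background).  Alpha is posterior-weighted, beta/theta frontal-weighted.
Blink artifacts are time-locked to the eye-closure stream and frontally
projected; occasional high-amplitude bursts and zeroed data-loss dropouts
are injected and logged.  No head-model forward projection is attempted.
"""

from __future__ import annotations

import numpy as np

from ..montage import CAP_LABELS, GRID_LABELS
from ..streams import ChannelTimeSeries
from .effects import BANDS_HZ, EffectConfig
from .scenario import ScenarioConfig

__all__ = ["synthesize_eeg", "EEG_RATE", "BACKGROUND_DB_AT_10HZ"]

EEG_RATE = 250.0
BACKGROUND_DB_AT_10HZ = -125.0   # 1/f background PSD at 10 Hz, dB re 1 V^2/Hz
SENSOR_NOISE_DB = -140.0         # flat per-electrode sensor noise
SHARED_BG_FRACTION = 0.5         # background power common to all channels

# amplitude weights of each band's oscillator per channel
CAP_BAND_WEIGHTS: dict[str, dict[str, float]] = {
    "alpha": {"P4": 1.0, "P3": 0.7, "Pz": 0.7, "O1": 0.8, "O2": 0.8,
              "CP1": 0.4, "CP2": 0.4},
    "beta": {"Fz": 1.0, "Fp1": 0.6, "Fp2": 0.6, "FC1": 0.5, "FC2": 0.5,
             "F7": 0.4, "F8": 0.4},
    "theta": {"Fz": 1.0, "Fp1": 0.8, "Fp2": 0.8, "FC1": 0.5, "FC2": 0.5},
}
# weights on the virtual-channel source contents of the grid
GRID_BAND_WEIGHTS: dict[str, dict[str, float]] = {
    "alpha": {"G_P": 1.0, "G_O": 0.8, "G_C": 0.3},
    "beta": {"G_FP": 1.0, "G_C": 0.3},
    "theta": {"G_FP": 1.0},
}
BLINK_GAIN_CAP = {"Fp1": 1.0, "Fp2": 1.0, "Fz": 0.6, "FC1": 0.25, "FC2": 0.25}
BLINK_GAIN_GRID = {"G_FP": 1.3, "G_EOG_U": 2.0, "G_EOG_D": 0.5}
BLINK_AMP_V = 120e-6


def _shaped_noise(n: int, fs: float, gain, rng: np.random.Generator) -> np.ndarray:
    """White noise spectrally shaped so the one-sided PSD is gain(f)^2 * 2/fs."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    X *= gain(f)
    return np.fft.irfft(X, n)


def _pink(n: int, fs: float, psd_at_10: float, rng) -> np.ndarray:
    def gain(f):
        fm = np.maximum(f, 0.5)
        g = np.sqrt(psd_at_10 * fs / 2.0) * np.sqrt(10.0 / fm)
        g[f == 0] = 0.0
        return g
    return _shaped_noise(n, fs, gain, rng)


def _band_unit(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Band-limited noise with one-sided PSD = 1 inside the band."""
    lo, hi = band
    def gain(f):
        g = np.zeros_like(f)
        g[(f >= lo) & (f <= hi)] = np.sqrt(fs / 2.0)
        return g
    return _shaped_noise(n, fs, gain, rng)


def background_band_mean(band: tuple[float, float],
                         psd_at_10: float = 10 ** (BACKGROUND_DB_AT_10HZ / 10)
                         ) -> float:
    """Analytic band-mean of the 1/f background PSD."""
    lo, hi = band
    return psd_at_10 * 10.0 * np.log(hi / lo) / (hi - lo)


def _pulse(fs: float, duration: float) -> np.ndarray:
    m = max(int(round(duration * fs)), 3)
    return np.hanning(m)


def _add_pulses(data: np.ndarray, row: int, times: np.ndarray, fs: float,
                shape: np.ndarray, gain: float) -> None:
    n = data.shape[1]
    m = len(shape)
    for t in times:
        i0 = int(round(t * fs))
        if i0 < 0 or i0 >= n:
            continue
        i1 = min(i0 + m, n)
        data[row, i0:i1] += gain * shape[: i1 - i0]


def _section_scale(targets_lin: np.ndarray, n: int, fs: float,
                   scenario: ScenarioConfig) -> np.ndarray:
    """Per-sample sqrt(PSD) scale following the section schedule."""
    sec = np.minimum((np.arange(n) / fs) // scenario.section_s,
                     scenario.n_sections - 1).astype(int)
    return np.sqrt(targets_lin[sec])


def synthesize_eeg(effects: EffectConfig,
                   scenario: ScenarioConfig,
                   condition: str,
                   rng: np.random.Generator,
                   blink_times: np.ndarray | None = None,
                   ) -> tuple[ChannelTimeSeries, ChannelTimeSeries,
                              dict[str, list[float]], list[dict],
                              list[tuple[float, float]]]:
    """Generate raw cap (24 ch) and grid (10 ch) EEG at 250 Hz.

    Returns ``(cap, grid, realized_band_targets_db, artifact_epochs,
    dropouts)``.  Realized targets include the per-cell dB jitter actually
    injected, keyed by band.
    """
    fs = EEG_RATE
    n = int(round(scenario.duration_s * fs))
    if blink_times is None:
        blink_times = np.array([])
    bg_psd = 10 ** (BACKGROUND_DB_AT_10HZ / 10)
    sens_psd = 10 ** (SENSOR_NOISE_DB / 10)

    # realized per-section oscillator PSD (linear), after cell noise
    realized: dict[str, list[float]] = {}
    osc_psd: dict[str, np.ndarray] = {}
    for band, rng_hz in BANDS_HZ.items():
        targets = effects.band_targets_db(band, condition) + \
            rng.normal(0.0, effects.band_cell_noise_db, scenario.n_sections)
        realized[band] = [float(v) for v in targets]
        lin = 10 ** (targets / 10) - background_band_mean(rng_hz, bg_psd)
        osc_psd[band] = np.maximum(lin, 1e-16)

    def band_track(band: str) -> np.ndarray:
        return _section_scale(osc_psd[band], n, fs, scenario)

    shared_cap = _pink(n, fs, bg_psd * SHARED_BG_FRACTION, rng)
    shared_grid = _pink(n, fs, bg_psd * SHARED_BG_FRACTION, rng)
    # one oscillatory source per band and system, projected onto channels
    # with spatial weights, so neighboring channels correlate realistically
    sources = {
        sysname: {band: band_track(band) * _band_unit(n, fs, BANDS_HZ[band],
                                                      rng)
                  for band in BANDS_HZ}
        for sysname in ("cap", "grid")
    }

    def content(label: str, weights: dict[str, dict[str, float]],
                shared: np.ndarray, sysname: str) -> np.ndarray:
        x = shared + _pink(n, fs, bg_psd * (1 - SHARED_BG_FRACTION), rng)
        for band in BANDS_HZ:
            w = weights[band].get(label, 0.0)
            if w:
                x = x + w * sources[sysname][band]
        return x

    def sensor(scale: float = 1.0) -> np.ndarray:
        return rng.standard_normal(n) * np.sqrt(sens_psd * fs / 2.0) * scale

    blink_shape = BLINK_AMP_V * _pulse(fs, effects.blink_duration_s)

    # --- cap ------------------------------------------------------------
    m1 = _pink(n, fs, sens_psd * 30, rng)
    m2 = _pink(n, fs, sens_psd * 30, rng)
    common_ref = 0.5 * (m1 + m2)
    cap = np.empty((len(CAP_LABELS), n))
    for i, lab in enumerate(CAP_LABELS):
        if lab == "M1":
            cap[i] = m1
        elif lab == "M2":
            cap[i] = m2
        else:
            cap[i] = content(lab, CAP_BAND_WEIGHTS, shared_cap, "cap") \
                + common_ref + sensor()
        gain = BLINK_GAIN_CAP.get(lab, 0.0)
        if gain:
            _add_pulses(cap, i, blink_times, fs, blink_shape, gain)

    # --- grid -----------------------------------------------------------
    grid = np.empty((len(GRID_LABELS), n))
    for i, lab in enumerate(GRID_LABELS):
        if lab in ("G_M2", "G_DRL"):
            grid[i] = shared_grid + sensor()
        else:
            grid[i] = content(lab, GRID_BAND_WEIGHTS, shared_grid, "grid") \
                + sensor()
        gain = BLINK_GAIN_GRID.get(lab, 0.0)
        if gain:
            _add_pulses(grid, i, blink_times, fs, blink_shape, gain)

    # --- bursts and dropouts ---------------------------------------------
    artifact_epochs: list[dict] = []
    n_bursts = rng.poisson(effects.artifact_rate_per_hour *
                           scenario.duration_s / 3600.0)
    m = int(round(effects.artifact_duration_s * fs))
    tt = np.arange(m) / fs
    burst_shape = np.sin(2 * np.pi * 5.0 * tt) * np.hanning(m)
    for _ in range(n_bursts):
        t0 = rng.uniform(0, scenario.duration_s - effects.artifact_duration_s)
        i0 = int(round(t0 * fs))
        amp = effects.artifact_amp_uv * 1e-6
        for arr in (cap, grid):
            gains = rng.uniform(0.5, 1.0, arr.shape[0])
            arr[:, i0:i0 + m] += amp * gains[:, None] * burst_shape[None, :]
        artifact_epochs.append({"t0": float(t0),
                                "t1": float(t0 + effects.artifact_duration_s),
                                "amp_uv": float(effects.artifact_amp_uv)})

    dropouts: list[tuple[float, float]] = []
    n_drop = rng.poisson(effects.dropout_rate_per_hour *
                         scenario.duration_s / 3600.0)
    for _ in range(n_drop):
        dur = rng.uniform(*effects.dropout_duration_s)
        t0 = rng.uniform(0, scenario.duration_s - dur)
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        cap[:, i0:i1] = 0.0
        grid[:, i0:i1] = 0.0
        dropouts.append((float(t0), float(t0 + dur)))

    cap_series = ChannelTimeSeries(cap, CAP_LABELS, fs, unit="V",
                                   meta={"system": "cap",
                                         "condition": condition})
    grid_series = ChannelTimeSeries(grid, GRID_LABELS, fs, unit="V",
                                    meta={"system": "grid",
                                          "condition": condition})
    return cap_series, grid_series, realized, artifact_epochs, dropouts
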