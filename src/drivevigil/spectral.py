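"""Epoching, artifact rejection, time sectioning, multitaper PSD and band
power in dB.

The analysis chain cuts a cleaned recording into contiguous 10 s epochs,
drops epochs that touch a data-loss window or exceed 200 uV peak-to-peak
on any channel, assigns the survivors to six equal time sections by epoch
start time, estimates each section's PSD from 1-30 Hz with DPSS
multitapers, and reduces it to band power (theta 4-8, alpha 8-12, beta
13-26 Hz, band edges inclusive) in dB re 1 V^2/Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from mne.time_frequency import psd_array_multitaper

from .streams import ChannelTimeSeries

__all__ = [
    "EpochSet",
    "BandDefinition",
    "BANDS",
    "epoch",
    "reject_epochs",
    "assign_sections",
    "psd_multitaper",
    "to_db",
    "band_power_sections",
    "SectionedPSD",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band and the channel it is read from per EEG system."""

    name: str
    fmin: float
    fmax: float
    cap_channel: str
    grid_channel: str

    def channel(self, system: str) -> str:
        return self.cap_channel if system == "cap" else self.grid_channel


#: parietal alpha, frontal beta and theta
BANDS: dict[str, BandDefinition] = {
    "alpha": BandDefinition("alpha", 8.0, 12.0, "P4", "P4_M2"),
    "beta": BandDefinition("beta", 13.0, 26.0, "Fz", "FPz_M2"),
    "theta": BandDefinition("theta", 4.0, 8.0, "Fz", "FPz_M2"),
}


@dataclass
class EpochSet:
    """Fixed-length epochs with kept/rejected bookkeeping."""

    data: np.ndarray                  # n_epochs x channels x samples
    start_times: np.ndarray           # seconds on the session clock
    length_s: float
    rate: float
    labels: list[str]
    kept: np.ndarray = field(default=None)        # bool per epoch
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kept is None:
            self.kept = np.ones(len(self.start_times), dtype=bool)
        if not self.reasons:
            self.reasons = [""] * len(self.start_times)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]


def epoch(series: ChannelTimeSeries, length_s: float = 10.0) -> EpochSet:
    """Contiguous non-overlapping epochs tiling the recording; a trailing
    partial epoch is dropped."""
    if series.duration < length_s:
        return EpochSet(np.empty((0, series.n_channels, 0)),
                        np.array([]), length_s, series.rate,
                        list(series.labels))
    m = int(round(length_s * series.rate))
    n = series.n_samples // m
    data = series.data[:, : n * m].reshape(series.n_channels, n, m)
    data = np.transpose(data, (1, 0, 2)).copy()
    starts = series.start_time + np.arange(n) * length_s
    return EpochSet(data, starts, length_s, series.rate, list(series.labels))


def reject_epochs(epochs: EpochSet,
                  loss_mask: list[tuple[float, float]] = (),
                  pp_threshold_uv: float = 200.0) -> EpochSet:
    """Reject epochs overlapping a loss window or exceeding the
    peak-to-peak amplitude threshold on any channel; reasons recorded."""
    if pp_threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    thr_v = pp_threshold_uv * 1e-6
    kept = epochs.kept.copy()
    reasons = list(epochs.reasons)
    for i, t0 in enumerate(epochs.start_times):
        if not kept[i]:
            continue
        t1 = t0 + epochs.length_s
        if any(a < t1 and t0 < b for a, b in loss_mask):
            kept[i] = False
            reasons[i] = "loss-overlap"
            continue
        pp = (epochs.data[i].max(axis=1) - epochs.data[i].min(axis=1)).max()
        if pp > thr_v:
            kept[i] = False
            reasons[i] = "amplitude"
    return EpochSet(epochs.data, epochs.start_times, epochs.length_s,
                    epochs.rate, epochs.labels, kept, reasons)


def assign_sections(epochs: EpochSet, session_duration: float,
                    n_sections: int = 6,
                    session_start: float = 0.0) -> np.ndarray:
    """0-based section index per epoch; boundaries at i*duration/n, each
    epoch assigned by where it starts (half-open bins)."""
    if n_sections < 1:
        raise ValueError("need at least one section")
    width = session_duration / n_sections
    rel = epochs.start_times - session_start
    return np.minimum((rel // width).astype(int), n_sections - 1)


def psd_multitaper(epoch_data: np.ndarray, rate: float,
                   fmin: float = 1.0, fmax: float = 30.0,
                   bandwidth: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue-weighted DPSS multitaper PSD averaged over epochs.

    ``epoch_data`` is n_epochs x channels x samples; returns
    (psd[channels, freqs] in V^2/Hz, freqs).  The linear PSD is averaged
    across epochs (dB conversion happens once, later).
    """
    if epoch_data.shape[0] == 0:
        raise ValueError("no kept epochs in section")
    psd, freqs = psd_array_multitaper(
        epoch_data, rate, fmin=fmin, fmax=fmax, bandwidth=bandwidth,
        adaptive=False, normalization="full", verbose="error")
    return psd.mean(axis=0), freqs


@dataclass
class SectionedPSD:
    """Per-section PSD on a common frequency grid (linear V^2/Hz)."""

    psd: list[np.ndarray | None]      # one per section, channels x freqs
    freqs: np.ndarray
    labels: list[str]
    epoch_counts: list[int]

    @property
    def n_sections(self) -> int:
        return len(self.psd)


def sectioned_psd(epochs: EpochSet, session_duration: float,
                  n_sections: int = 6, fmin: float = 1.0,
                  fmax: float = 30.0, bandwidth: float = 0.8) -> SectionedPSD:
    """Multitaper PSD per section over kept epochs; a section with no kept
    epoch is flagged missing (None), never silently zero."""
    sec = assign_sections(epochs, session_duration, n_sections)
    psds: list[np.ndarray | None] = []
    counts: list[int] = []
    freqs = None
    for s in range(n_sections):
        idx = np.where(epochs.kept & (sec == s))[0]
        counts.append(len(idx))
        if len(idx) == 0:
            psds.append(None)
            continue
        p, freqs = psd_multitaper(epochs.data[idx], epochs.rate,
                                  fmin, fmax, bandwidth)
        psds.append(p)
    if freqs is None:
        raise ValueError("no section has any kept epoch")
    return SectionedPSD(psds, freqs, list(epochs.labels), counts)


def to_db(power) -> np.ndarray:
    """Linear power (V^2/Hz) to dB: 10*log10(power)."""
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power must be positive for dB conversion")
    return 10.0 * np.log10(power)


def band_power_sections(spsd: SectionedPSD, band: BandDefinition,
                        channel: str) -> pd.DataFrame:
    """Band power per section at one channel, in dB.

    The linear PSD bins with frequency in [fmin, fmax] (inclusive on both
    edges) are averaged, then converted to dB once.  Missing sections get
    NaN.
    """
    if channel not in spsd.labels:
        raise KeyError(f"band channel {channel!r} not present")
    ci = spsd.labels.index(channel)
    sel = (spsd.freqs >= band.fmin) & (spsd.freqs <= band.fmax)
    rows = []
    for s, p in enumerate(spsd.psd):
        if p is None:
            val = np.nan
        else:
            val = float(to_db(p[ci, sel].mean()))
        rows.append({"section": s + 1, "band": band.name, "channel": channel,
                     "value_db": val, "n_epochs": spsd.epoch_counts[s]})
    return pd.DataFrame(rows)
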