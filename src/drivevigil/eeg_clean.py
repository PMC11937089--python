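"""EEG preprocessing: FIR bandpass, bad-channel handling, mastoid
re-referencing, virtual grid channels, and Artifact Subspace
Reconstruction (ASR).

The cleaning chain mirrors common mobile-EEG practice: a broad 0.1-40 Hz
bandpass on each system, bad-channel interpolation (cap only — the sparse
grid cannot be interpolated), re-referencing of the cap to averaged
mastoids, derivation of virtual 10-20 channels from grid differences,
merging, a second 1-40 Hz bandpass, and ASR to reconstruct
artifact-dominated subspaces from a clean calibration window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import CAP_POSITIONS, VirtualChannelMap, default_virtual_map
from .streams import ChannelTimeSeries

__all__ = [
    "fir_bandpass",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "reref_mastoids",
    "derive_virtual_channels",
    "AsrModel",
    "asr_fit",
    "asr_apply",
    "clean_merged",
]


def design_bandpass(low: float, high: float, rate: float) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase bandpass kernel.

    Transition width is ``max(0.5 Hz, 0.25 * low)``; the Hamming window
    gives ~53 dB stopband attenuation and <0.1 dB passband ripple.
    """
    nyq = rate / 2.0
    if not 0.0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    trans = max(0.5, 0.25 * low)
    numtaps = int(np.ceil(3.3 * rate / trans)) | 1  # odd for exact linear phase
    return signal.firwin(numtaps, [max(low, 1e-6), high], window="hamming",
                         pass_zero=False, fs=rate)


def fir_bandpass(series: ChannelTimeSeries, low: float, high: float
                 ) -> ChannelTimeSeries:
    """Zero-phase FIR bandpass (single linear-phase pass, delay removed)."""
    taps = design_bandpass(low, high, series.rate)
    half = len(taps) // 2
    padded = np.pad(series.data, ((0, 0), (half, half)), mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="valid", axes=1)
    res = series.copy()
    res.data = out
    res.meta.setdefault("filters", []).append((low, high))
    return res


def detect_bad_channels(series: ChannelTimeSeries,
                        flat_floor: float = 1e-8,
                        noisy_ratio: float = 5.0,
                        flat_ratio: float = 0.02,
                        corr_threshold: float = 0.2,
                        ) -> set[str]:
    """Flag channels with implausible amplitude or no shared signal.

    A channel is *flat* if its SD is below an absolute floor or a small
    fraction of the median channel SD, *noisy* if its SD exceeds
    ``noisy_ratio`` times the median, and *disconnected* if its best
    absolute correlation with any other channel falls below
    ``corr_threshold``.  Deterministic given the data.
    """
    if series.duration < 60.0:
        raise ValueError("bad-channel detection needs >= 60 s of data")
    sds = series.data.std(axis=1)
    med = np.median(sds[sds > 0]) if np.any(sds > 0) else 0.0
    bads: set[str] = set()
    for lab, sd in zip(series.labels, sds):
        if sd < flat_floor or (med > 0 and sd < flat_ratio * med):
            bads.add(lab)
        elif med > 0 and sd > noisy_ratio * med:
            bads.add(lab)
    good_idx = [i for i, l in enumerate(series.labels) if l not in bads]
    if corr_threshold > 0 and len(good_idx) >= 3:
        sub = series.data[good_idx]
        c = np.corrcoef(sub)
        np.fill_diagonal(c, 0.0)
        best = np.nanmax(np.abs(c), axis=1)
        # relative rule: a channel is disconnected only when the rest of
        # the montage shares signal and this one does not (an all-i.i.d.
        # montage flags nothing)
        med_best = float(np.median(best))
        for k, i in enumerate(good_idx):
            if best[k] < corr_threshold and best[k] < 0.5 * med_best:
                bads.add(series.labels[i])
    return bads


def interpolate_bad_channels(series: ChannelTimeSeries,
                             bads: set[str] | list[str],
                             positions: dict[str, tuple[float, float]] | None = None,
                             n_neighbors: int = 4) -> ChannelTimeSeries:
    """Replace cap channels by a distance-weighted (1/d^2) average of the
    nearest good neighbors.  The sparse around-ear grid cannot be
    interpolated this way and is rejected."""
    positions = positions or CAP_POSITIONS
    bads = set(bads)
    if not bads:
        return series.copy()
    for b in bads:
        if b not in series.labels:
            raise KeyError(f"unknown channel {b!r}")
        if b not in positions:
            raise ValueError(
                f"channel {b!r} has no cap position; interpolation is not "
                "possible for the around-ear grid"
            )
    out = series.copy()
    good = [l for l in series.labels if l not in bads and l in positions]
    for b in bads:
        bx, by = positions[b]
        dists = np.array([np.hypot(positions[g][0] - bx,
                                   positions[g][1] - by) for g in good])
        order = np.argsort(dists)[:n_neighbors]
        if len(order) < 3:
            raise ValueError(f"fewer than 3 good neighbors for {b!r}")
        w = 1.0 / np.maximum(dists[order], 1e-6) ** 2
        w /= w.sum()
        rows = [series.labels.index(good[i]) for i in order]
        out.data[series.labels.index(b)] = w @ series.data[rows]
    out.meta.setdefault("interpolated", []).extend(sorted(bads))
    return out


def reref_mastoids(series: ChannelTimeSeries) -> ChannelTimeSeries:
    """Re-reference every cap channel to the averaged mastoids (M1+M2)/2.

    Refuses a second application (the operation is not idempotent)."""
    if series.meta.get("reref") == "mastoids":
        raise ValueError("data are already mastoid-referenced")
    for m in ("M1", "M2"):
        if m not in series.labels:
            raise KeyError(f"mastoid channel {m!r} missing")
    ref = 0.5 * (series.data[series.labels.index("M1")] +
                 series.data[series.labels.index("M2")])
    out = series.copy()
    out.data = series.data - ref[None, :]
    out.meta["reref"] = "mastoids"
    return out


def derive_virtual_channels(grid: ChannelTimeSeries,
                            vmap: VirtualChannelMap | None = None
                            ) -> ChannelTimeSeries:
    """Linear virtual 10-20 approximations from grid channel differences."""
    return (vmap or default_virtual_map()).apply(grid)


# ---------------------------------------------------------------------------
# Artifact Subspace Reconstruction
# ---------------------------------------------------------------------------

@dataclass
class AsrModel:
    """Calibration state of the ASR cleaner."""

    mixing: np.ndarray                 # channels x components (orthonormal)
    thresholds: np.ndarray             # per-component variance ceilings
    window_s: float = 0.5
    cutoff_k: float = 20.0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.thresholds <= 0):
            raise ValueError("component thresholds must be positive")


def _sliding_windows(n: int, win: int, hop: int) -> list[tuple[int, int]]:
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if not starts:
        return [(0, n)]
    if starts[-1] + win < n:
        starts.append(n - win)
    return [(s, s + win) for s in starts]


def asr_fit(series: ChannelTimeSeries,
            window_s: float = 0.5,
            cutoff_k: float = 20.0,
            calib_fraction: float = 0.1,
            allow_rank_deficient: bool = False) -> AsrModel:
    """Calibrate ASR on the cleanest stretches of the recording.

    The cleanest ``calib_fraction`` of 1 s windows by mean channel RMS form
    the calibration data; its PCA gives the component basis, and each
    component's rejection threshold is ``mean + k * SD`` of its variance
    across calibration windows of length ``window_s``.
    """
    if series.duration < 60.0:
        raise ValueError("ASR calibration needs >= 60 s of data")
    fs = series.rate
    sec = int(fs)
    nwin = series.n_samples // sec
    rms = np.array([
        np.sqrt(np.mean(series.data[:, i * sec:(i + 1) * sec] ** 2))
        for i in range(nwin)
    ])
    # at least 60 s of calibration even for short recordings
    keep = min(max(int(np.ceil(calib_fraction * nwin)), 60), nwin)
    order = np.argsort(rms)[:keep]
    calib = np.concatenate(
        [series.data[:, i * sec:(i + 1) * sec] for i in sorted(order)], axis=1)

    calib = calib - calib.mean(axis=1, keepdims=True)
    cov = calib @ calib.T / calib.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] <= 1e-12 * evals[-1]:
        if not allow_rank_deficient:
            raise ValueError("rank-deficient calibration data")
        # drop null components (e.g. interpolated channels are exact
        # combinations); the retained basis spans all observed variance
        keep_c = evals > 1e-12 * evals[-1]
        evals, evecs = evals[keep_c], evecs[:, keep_c]

    win = int(window_s * fs)
    comps = evecs.T @ calib
    wvars = np.array([
        comps[:, a:b].var(axis=1)
        for a, b in _sliding_windows(comps.shape[1], win, win)
    ])
    thr = wvars.mean(axis=0) + cutoff_k * wvars.std(axis=0)
    thr = np.maximum(thr, 1e-30)
    return AsrModel(mixing=evecs, thresholds=thr, window_s=window_s,
                    cutoff_k=cutoff_k, labels=list(series.labels))


def asr_apply(series: ChannelTimeSeries, model: AsrModel) -> ChannelTimeSeries:
    """Reconstruct artifact windows from the retained subspace.

    Sliding half-overlapping windows are projected onto the calibration
    components; components whose in-window variance exceeds their
    threshold are zeroed and the window is rebuilt from the rest, with
    Hann overlap-add so clean stretches pass through untouched.
    """
    if model.labels and model.labels != series.labels:
        raise ValueError("channel set differs from the fitted model")
    fs = series.rate
    win = int(model.window_s * fs)
    hop = win // 2
    n = series.n_samples
    V = model.mixing
    out = np.zeros_like(series.data)
    wsum = np.zeros(n)
    taper = np.hanning(win)
    for a, b in _sliding_windows(n, win, hop):
        w = taper[: b - a] if b - a == win else np.hanning(b - a)
        seg = series.data[:, a:b]
        comps = V.T @ seg
        bad = comps.var(axis=1) > model.thresholds
        if np.any(bad):
            comps = comps.copy()
            comps[bad] = 0.0
            seg = V @ comps
        out[:, a:b] += seg * w[None, :]
        wsum[a:b] += w
    # boundary samples carry no taper weight; pass the input through there
    uncovered = wsum < 1e-6
    wsum[uncovered] = 1.0
    res = series.copy()
    res.data = out / wsum[None, :]
    res.data[:, uncovered] = series.data[:, uncovered]
    res.meta["asr"] = {"window_s": model.window_s, "cutoff_k": model.cutoff_k}
    return res


def clean_merged(merged: ChannelTimeSeries,
                 cutoff_k: float = 20.0) -> ChannelTimeSeries:
    """Second bandpass (1-40 Hz) followed by ASR fit + apply."""
    filt = fir_bandpass(merged, 1.0, 40.0)
    rank_ok = not merged.meta.get("interpolated")
    model = asr_fit(filt, cutoff_k=cutoff_k,
                    allow_rank_deficient=not rank_ok)
    return asr_apply(filt, model)
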