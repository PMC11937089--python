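"""Ocular and cardiac drowsiness features: PERCLOS and SDRR/BPM.

PERCLOS is the mean eye-closure fraction (1 - openness / max openness,
averaged over the valid eyes) over a 60 s window sliding in 1 s steps,
expressed in percent.  Heart-rate variability is summarized per 1-minute
window as SDRR, the sample standard deviation of successive R-to-R
intervals in milliseconds, alongside BPM as the per-window R-peak count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .streams import ChannelTimeSeries

__all__ = ["perclos", "section_means", "detect_rpeaks", "RRSeries",
           "hrv_windows", "hrv_sections"]


def _closure(openness: np.ndarray, valid: np.ndarray,
             max_quantile: float) -> np.ndarray:
    """Per-sample closure fraction for one eye; NaN where invalid."""
    ok = valid > 0.5
    if not np.any(ok):
        return np.full(openness.shape, np.nan)
    mx = np.quantile(openness[ok], max_quantile)
    if mx <= 0:
        raise ValueError("non-positive maximum openness")
    c = 1.0 - openness / mx
    c = np.clip(c, 0.0, 1.0)
    c[~ok] = np.nan
    return c


def perclos(eyes: ChannelTimeSeries,
            window_s: float = 60.0,
            step_s: float = 1.0,
            max_quantile: float = 0.995) -> pd.DataFrame:
    """Sliding-window percentage of eye closure.

    Openness is normalized per eye by the subject's maximum openness
    (robustly, the ``max_quantile`` quantile of valid samples); closure is
    averaged over the valid eyes at each timepoint (a single eye is used
    when the other is invalid; points with both eyes invalid are dropped);
    each 60 s window's mean closure x 100 is emitted every ``step_s``
    seconds, stamped with the window start.  A window with no valid point
    yields NaN.
    """
    need = {"left_openness", "left_valid", "right_openness", "right_valid"}
    if not need <= set(eyes.labels):
        raise KeyError(f"eye stream must contain {sorted(need)}")
    if eyes.duration < window_s:
        raise ValueError("need at least one full window of data")

    def ch(name):
        return eyes.data[eyes.labels.index(name)]

    left = _closure(ch("left_openness"), ch("left_valid"), max_quantile)
    right = _closure(ch("right_openness"), ch("right_valid"), max_quantile)
    # mean of the valid eyes; NaN iff both invalid
    cnt = (~np.isnan(left)).astype(float) + (~np.isnan(right)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        both = (np.nan_to_num(left) + np.nan_to_num(right)) / cnt
    both[cnt == 0] = np.nan

    # accumulate per-step bins, then roll a window_s-long box over them
    fs = eyes.rate
    step = int(round(step_s * fs))
    nbins = int(eyes.n_samples // step)
    x = both[: nbins * step].reshape(nbins, step)
    bin_sum = np.nansum(x, axis=1)
    bin_cnt = np.sum(~np.isnan(x), axis=1)
    k = int(round(window_s / step_s))
    if nbins < k:
        raise ValueError("need at least one full window of data")
    csum = np.concatenate([[0.0], np.cumsum(bin_sum)])
    ccnt = np.concatenate([[0], np.cumsum(bin_cnt)])
    wins_sum = csum[k:] - csum[:-k]
    wins_cnt = ccnt[k:] - ccnt[:-k]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * wins_sum / wins_cnt
    vals[wins_cnt == 0] = np.nan
    times = eyes.start_time + np.arange(nbins - k + 1) * step_s
    return pd.DataFrame({"time": times, "perclos": vals})


def section_means(series: pd.DataFrame, session_duration: float,
                  n_sections: int = 6, value_col: str | None = None,
                  time_col: str = "time") -> pd.DataFrame:
    """Average a windowed feature series over six equal time sections.

    Each emitted value belongs to the section containing its timestamp;
    an empty section yields NaN.
    """
    if value_col is None:
        value_col = [c for c in series.columns if c != time_col][0]
    width = session_duration / n_sections
    sec = np.minimum((series[time_col].to_numpy() // width).astype(int),
                     n_sections - 1)
    out = []
    for s in range(n_sections):
        v = series[value_col].to_numpy()[sec == s]
        v = v[~np.isnan(v)]
        out.append({"section": s + 1,
                    "value": float(np.mean(v)) if len(v) else np.nan,
                    "n_windows": int(len(v))})
    return pd.DataFrame(out)


@dataclass
class RRSeries:
    """Detected R-peak times and the successive R-R intervals."""

    peak_times: np.ndarray           # seconds
    rr_ms: np.ndarray                # len(peak_times) - 1 intervals

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, float)
        self.rr_ms = np.asarray(self.rr_ms, float)
        if np.any(self.rr_ms <= 0):
            raise ValueError("R-R intervals must be positive")


def detect_rpeaks(ecg: ChannelTimeSeries, prominence: float = 0.5,
                  refractory_s: float = 0.2) -> RRSeries:
    """R-peak detection by prominence-gated local maxima.

    ``prominence`` is in the signal's own units and is meant to be tuned
    per subject; a physiological refractory constraint enforces >= 200 ms
    between accepted peaks.
    """
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    x = ecg.data[0]
    idx, _ = signal.find_peaks(x, prominence=prominence,
                               distance=max(int(refractory_s * ecg.rate), 1))
    if len(idx) == 0:
        raise ValueError(
            "no R-peaks found; review the prominence setting for this subject"
        )
    t = ecg.start_time + idx / ecg.rate
    return RRSeries(t, np.diff(t) * 1000.0)


def hrv_windows(rr: RRSeries, window_s: float = 60.0,
                t0: float = 0.0, duration: float | None = None
                ) -> pd.DataFrame:
    """Per-window BPM (peak count) and SDRR (sample SD, n-1 denominator).

    An interval belongs to the window containing its terminating peak; a
    window with fewer than 2 intervals is emitted missing.
    """
    if duration is None:
        duration = rr.peak_times[-1] - t0
    nwin = int(np.ceil(duration / window_s))
    term = rr.peak_times[1:]
    rows = []
    for w in range(nwin):
        a, b = t0 + w * window_s, t0 + (w + 1) * window_s
        in_w = (term >= a) & (term < b)
        n_peaks = int(np.sum((rr.peak_times >= a) & (rr.peak_times < b)))
        ints = rr.rr_ms[in_w]
        rows.append({
            "time": a,
            "bpm": n_peaks,
            "sdrr_ms": float(np.std(ints, ddof=1)) if len(ints) >= 2 else np.nan,
            "n_intervals": int(len(ints)),
        })
    return pd.DataFrame(rows)


def hrv_sections(rr: RRSeries, session_duration: float,
                 n_sections: int = 6, window_s: float = 60.0) -> pd.DataFrame:
    """Section means of the 1-minute SDRR (and BPM) windows."""
    wins = hrv_windows(rr, window_s, t0=0.0, duration=session_duration)
    sd = section_means(wins, session_duration, n_sections,
                       value_col="sdrr_ms")
    bpm = section_means(wins, session_duration, n_sections, value_col="bpm")
    sd = sd.rename(columns={"value": "sdrr_ms"})
    sd["bpm"] = bpm["value"]
    return sd
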