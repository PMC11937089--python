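"""Driving-performance, hazard-response, PVT and questionnaire features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streams import ChannelTimeSeries, EventList

__all__ = [
    "rmse_lane",
    "ResponseRecord",
    "match_responses",
    "detection_accuracy",
    "drt_sections",
    "pvt_score",
    "nasa_tlx_score",
]

MIN_DRT_S = 0.2   # faster responses are late answers to the previous car


def rmse_lane(telemetry: ChannelTimeSeries, session_duration: float,
              n_sections: int = 6) -> pd.DataFrame:
    """Per-section root-mean-square lateral deviation from lane center.

    The deviation is taken about lane center (zero), not about the mean;
    lane keeping in the automated condition is a controller property, so
    the caller is expected to run this on manual-condition telemetry (a
    flag is set when it is not).
    """
    x = telemetry.data[telemetry.labels.index("lateral_m")]
    t = telemetry.times()
    width = session_duration / n_sections
    sec = np.minimum((t // width).astype(int), n_sections - 1)
    rows = []
    for s in range(n_sections):
        v = x[sec == s]
        rows.append({"section": s + 1,
                     "rmse_m": float(np.sqrt(np.mean(v ** 2))) if len(v)
                     else np.nan,
                     "n_samples": int(len(v))})
    df = pd.DataFrame(rows)
    df.attrs["condition"] = telemetry.meta.get("condition", "unknown")
    df.attrs["flagged_automated"] = df.attrs["condition"] == "PAD"
    return df


@dataclass(frozen=True)
class ResponseRecord:
    stimulus_time: float
    stimulus_kind: str              # car_safe | car_unsafe
    press_time: float | None
    drt_s: float | None             # None when unmatched or < 200 ms
    outcome: str                    # hit | miss | false_alarm_press


def match_responses(cars: EventList, presses: EventList,
                    window_s: float = 3.5) -> list[ResponseRecord]:
    """Match button presses to unsafe-car stimuli.

    Each press, in time order, consumes the most recent unmatched unsafe
    stimulus whose visibility window (onset + ``window_s``) contains it.
    Hits with latency < 200 ms keep their hit outcome but are excluded
    from latency statistics; unmatched unsafe stimuli are misses and
    unmatched presses are false alarms.
    """
    unsafe = [e for e in cars.of_kind("car_unsafe")]
    taken = [False] * len(unsafe)
    press_match: dict[int, int] = {}
    press_times = sorted(e.time for e in presses.of_kind("press"))
    false_alarms = []
    for pi, pt in enumerate(press_times):
        matched = None
        for si in range(len(unsafe) - 1, -1, -1):
            st = unsafe[si].time
            if st > pt:
                continue
            if pt < st + window_s and not taken[si]:
                matched = si
            break  # only the most recent stimulus at or before the press
        if matched is None:
            false_alarms.append(pt)
        else:
            taken[matched] = True
            press_match[matched] = pi

    records: list[ResponseRecord] = []
    for si, e in enumerate(unsafe):
        if si in press_match:
            pt = press_times[press_match[si]]
            drt = pt - e.time
            records.append(ResponseRecord(
                e.time, "car_unsafe", pt,
                drt if drt >= MIN_DRT_S else None, "hit"))
        else:
            records.append(ResponseRecord(e.time, "car_unsafe", None, None,
                                          "miss"))
    for pt in false_alarms:
        records.append(ResponseRecord(pt, "car_safe", pt, None,
                                      "false_alarm_press"))
    return records


def detection_accuracy(records: list[ResponseRecord]) -> float:
    """Percent of unsafe stimuli answered with a press."""
    unsafe = [r for r in records if r.stimulus_kind == "car_unsafe"]
    if not unsafe:
        raise ValueError("no unsafe stimuli to score")
    hits = sum(r.outcome == "hit" for r in unsafe)
    return 100.0 * hits / len(unsafe)


def drt_sections(records: list[ResponseRecord], session_duration: float,
                 n_sections: int = 6) -> pd.DataFrame:
    """Mean hit latency per section (stimulus-time binning)."""
    width = session_duration / n_sections
    rows = []
    for s in range(n_sections):
        a, b = s * width, (s + 1) * width
        vals = [r.drt_s for r in records
                if r.outcome == "hit" and r.drt_s is not None
                and a <= r.stimulus_time < b]
        rows.append({"section": s + 1,
                     "drt_s": float(np.mean(vals)) if vals else np.nan,
                     "n_hits": len(vals)})
    return pd.DataFrame(rows)


def pvt_score(stimuli: np.ndarray, responses: np.ndarray,
              max_rt_s: float = 1.0, min_rt_s: float = 0.1
              ) -> tuple[float | None, int]:
    """Mean valid psychomotor-vigilance reaction time in ms.

    Each stimulus is matched to the first response after it; only
    latencies in (``min_rt_s``, ``max_rt_s``] are valid.  Returns
    ``(mean_ms, n_valid)``; the mean is None when nothing survives.
    """
    stimuli = np.sort(np.asarray(stimuli, float))
    responses = np.sort(np.asarray(responses, float))
    if len(stimuli) == 0:
        raise ValueError("need at least one stimulus")
    rts = []
    j = 0
    for st in stimuli:
        while j < len(responses) and responses[j] <= st:
            j += 1
        if j < len(responses):
            rt = responses[j] - st
            if min_rt_s < rt <= max_rt_s:
                rts.append(rt)
                j += 1
    if not rts:
        return None, 0
    return float(np.mean(rts) * 1000.0), len(rts)


def nasa_tlx_score(subscales) -> float:
    """Overall task load: arithmetic mean of the six 0-20 subscales
    (mental, physical and temporal demand, performance, effort,
    frustration)."""
    vals = np.asarray(subscales, float)
    if vals.shape != (6,):
        raise ValueError("exactly six subscale values are required")
    if np.any(vals < 0) or np.any(vals > 20):
        raise ValueError("subscale values must lie in [0, 20]")
    return float(vals.mean())
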