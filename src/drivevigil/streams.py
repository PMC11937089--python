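"""Containers and temporal bookkeeping for multi-stream driving sessions.

A recording session bundles several uniformly sampled streams (EEG, ECG,
eye openness, driving telemetry) plus sparse event lists (hazard cars,
button presses, wind gusts, crashes) on one shared session clock.  Time is
float seconds; every interval is half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ChannelTimeSeries",
    "Event",
    "EventList",
    "MultiStreamSession",
    "mark_data_loss",
    "resample",
    "merge_streams",
    "align_streams",
]

EVENT_KINDS = {
    "car_safe",
    "car_unsafe",
    "press",
    "gust",
    "crash",
    "pvt_stim",
    "pvt_resp",
}


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    payload: dict = field(default_factory=dict)


class EventList:
    """Time-sorted list of typed events."""

    def __init__(self, events: Iterable[Event] = ()):
        evs = sorted(events, key=lambda e: e.time)
        for e in evs:
            if not np.isfinite(e.time):
                raise ValueError(f"non-finite event time: {e.time!r}")
            if e.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind: {e.kind!r}")
        self.events: list[Event] = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def times(self, kind: str | None = None) -> np.ndarray:
        return np.array(
            [e.time for e in self.events if kind is None or e.kind == kind]
        )

    def of_kind(self, *kinds: str) -> "EventList":
        return EventList(e for e in self.events if e.kind in kinds)

    def shifted(self, dt: float) -> "EventList":
        return EventList(replace(e, time=e.time + dt) for e in self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [e.time for e in self.events],
                "kind": [e.kind for e in self.events],
                "payload": [json.dumps(e.payload) for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        return cls(
            Event(float(t), str(k), json.loads(p) if isinstance(p, str) else {})
            for t, k, p in zip(df["time"], df["kind"], df.get("payload", [""] * len(df)))
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventList":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


@dataclass
class ChannelTimeSeries:
    """Uniformly sampled multichannel signal with a data-loss mask.

    ``data`` is channels x samples in physical units (volts for EEG/ECG).
    ``loss_mask`` is a list of half-open ``[t0, t1)`` intervals on the
    session clock marking unusable stretches.
    """

    data: np.ndarray
    labels: list[str]
    rate: float
    start_time: float = 0.0
    unit: str = "V"
    loss_mask: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = list(self.labels)
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        for t0, t1 in self.loss_mask:
            if t1 < t0:
                raise ValueError(f"negative-length loss interval [{t0}, {t1})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def pick(self, labels: Sequence[str]) -> "ChannelTimeSeries":
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"missing channel(s): {missing}")
        idx = [self.labels.index(l) for l in labels]
        return ChannelTimeSeries(
            self.data[idx].copy(), list(labels), self.rate, self.start_time,
            self.unit, list(self.loss_mask), dict(self.meta),
        )

    def copy(self) -> "ChannelTimeSeries":
        return ChannelTimeSeries(
            self.data.copy(), list(self.labels), self.rate, self.start_time,
            self.unit, list(self.loss_mask), dict(self.meta),
        )

    def masked_duration(self) -> float:
        return sum(t1 - t0 for t0, t1 in merge_intervals(self.loss_mask))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.T, columns=self.labels)
        df.insert(0, "time", self.times())
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, rate: float | None = None,
                 unit: str = "V") -> "ChannelTimeSeries":
        df = pd.read_csv(path)
        t = df["time"].to_numpy(float)
        if rate is None:
            if len(t) < 2:
                raise ValueError("cannot infer rate from fewer than 2 samples")
            rate = 1.0 / float(np.median(np.diff(t)))
        labels = [c for c in df.columns if c != "time"]
        return cls(df[labels].to_numpy(float).T, labels, rate,
                   start_time=float(t[0]), unit=unit)


def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals, merged and sorted."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def mark_data_loss(series: ChannelTimeSeries,
                   gaps: Iterable[tuple[float, float]],
                   window_s: float = 0.5,
                   overlap_s: float = 0.1) -> ChannelTimeSeries:
    """Cover each loss gap with fixed-length windows and grow the mask.

    Windows of ``window_s`` advance in steps of ``window_s - overlap_s``
    (0.5 s segments with 100 ms overlap by default), the first anchored at
    the gap onset, until the gap is covered.  The existing mask never
    shrinks: the new mask is the union of old windows and new ones.
    """
    step = window_s - overlap_s
    if step <= 0:
        raise ValueError("overlap must be shorter than the window")
    new = list(series.loss_mask)
    for g0, g1 in gaps:
        g0, g1 = float(g0), float(g1)
        if g1 < g0:
            raise ValueError(f"negative-length gap [{g0}, {g1})")
        if g1 == g0:
            continue
        if g0 < series.start_time or g1 > series.end_time + 1e-9:
            raise ValueError(f"gap [{g0}, {g1}) outside series span")
        t = g0
        while True:
            new.append((t, t + window_s))
            if t + window_s >= g1:
                break
            t += step
    out = series.copy()
    out.loss_mask = merge_intervals(new)
    return out


def resample(series: ChannelTimeSeries, target_rate: float) -> ChannelTimeSeries:
    """Band-limited polyphase resampling; the loss mask is carried over
    unchanged (it lives in seconds, not samples)."""
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if np.isclose(target_rate, series.rate):
        return series.copy()
    ratio = Fraction(target_rate / series.rate).limit_denominator(1000)
    data = signal.resample_poly(series.data, ratio.numerator,
                                ratio.denominator, axis=1)
    return ChannelTimeSeries(data, list(series.labels), target_rate,
                             series.start_time, series.unit,
                             list(series.loss_mask), dict(series.meta))


def merge_streams(cap: ChannelTimeSeries, grid: ChannelTimeSeries,
                  grid_tag: str = "_grid") -> ChannelTimeSeries:
    """Combine cap and grid EEG into one container.

    Grid labels whose name collides with a cap label get the ``_grid``
    origin tag; rates must match and the overlapping time support is kept.
    Loss masks are unioned.
    """
    if not np.isclose(cap.rate, grid.rate):
        raise ValueError("resample to a common rate before merging")
    t0 = max(cap.start_time, grid.start_time)
    t1 = min(cap.end_time, grid.end_time)
    if t1 <= t0:
        raise ValueError("streams do not overlap in time")
    n = int(round((t1 - t0) * cap.rate))

    def crop(s: ChannelTimeSeries) -> np.ndarray:
        i0 = int(round((t0 - s.start_time) * s.rate))
        return s.data[:, i0:i0 + n]

    grid_labels = [
        l if l not in cap.labels else l + grid_tag for l in grid.labels
    ]
    labels = list(cap.labels) + grid_labels
    if len(set(labels)) != len(labels):
        dupes = {l for l in labels if labels.count(l) > 1}
        raise ValueError(f"duplicate labels after tagging: {sorted(dupes)}")
    data = np.vstack([crop(cap), crop(grid)])
    mask = merge_intervals(list(cap.loss_mask) + list(grid.loss_mask))
    meta = {**grid.meta, **cap.meta, "grid_labels": grid_labels}
    return ChannelTimeSeries(data, labels, cap.rate, t0, cap.unit, mask, meta)


@dataclass
class MultiStreamSession:
    """One driving condition's worth of time-aligned streams and events."""

    streams: dict[str, ChannelTimeSeries]
    events: EventList
    meta: dict = field(default_factory=dict)

    @property
    def condition(self) -> str:
        return self.meta.get("condition", "unknown")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"meta": self.meta, "streams": {}}
        for name, s in self.streams.items():
            s.to_csv(out / f"{name}.csv")
            manifest["streams"][name] = {
                "rate": s.rate,
                "unit": s.unit,
                "start_time": s.start_time,
                "loss_mask": [list(iv) for iv in s.loss_mask],
            }
        self.events.to_csv(out / "events.csv")
        (out / "session.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "MultiStreamSession":
        p = Path(in_dir)
        manifest = json.loads((p / "session.json").read_text())
        streams = {}
        for name, info in manifest["streams"].items():
            s = ChannelTimeSeries.from_csv(p / f"{name}.csv", rate=info["rate"],
                                           unit=info["unit"])
            s.start_time = info["start_time"]
            s.loss_mask = [tuple(iv) for iv in info["loss_mask"]]
            streams[name] = s
        return cls(streams, EventList.from_csv(p / "events.csv"),
                   manifest["meta"])


def _match_events(a: np.ndarray, b: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one nearest matching of two sorted time vectors."""
    ia: list[int] = []
    ib: list[int] = []
    j = 0
    for i, t in enumerate(a):
        while j < len(b) and b[j] < t - tol:
            j += 1
        if j < len(b) and abs(b[j] - t) <= tol:
            ia.append(i)
            ib.append(j)
            j += 1
    return np.array(ia, int), np.array(ib, int)


def align_streams(session: MultiStreamSession,
                  reference_events: EventList,
                  kind: str = "car_safe",
                  tol: float = 1.0) -> MultiStreamSession:
    """Correct a constant clock offset of the session's event stream.

    ``reference_events`` come from a trusted timing channel (the study's
    photodiode); events of ``kind`` in the session's event stream are
    matched one-to-one to reference times within ``tol`` seconds, the mean
    mismatch is removed, and the residual per-event error is reported in
    ``session.meta['alignment']``.
    """
    ref = np.sort(reference_events.times(kind))
    obs = np.sort(session.events.times(kind))
    ia, ib = _match_events(ref, obs, tol)
    if len(ia) < 2:
        raise ValueError(
            f"need >= 2 matched {kind!r} events to estimate an offset, "
            f"got {len(ia)}"
        )
    offset = float(np.mean(obs[ib] - ref[ia]))
    residual = obs[ib] - offset - ref[ia]
    out = MultiStreamSession(
        {k: v for k, v in session.streams.items()},
        session.events.shifted(-offset),
        dict(session.meta),
    )
    out.meta["alignment"] = {
        "offset_s": offset,
        "n_matched": int(len(ia)),
        "residual_rms_s": float(np.sqrt(np.mean(residual ** 2))),
        "residual_max_s": float(np.max(np.abs(residual))),
    }
    return out
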