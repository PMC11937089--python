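"""Driving-scenario configuration and event generation.

The simulated scenario is a monotonous nighttime highway drive at a fixed
80 km/h: perpendicular wind gusts of random strength hit the car every
260-330 m with strictly alternating direction, and white cars parked on
the right shoulder appear every 4-6 s, 12-15 % of them protruding unsafely
into the lane (never two unsafe cars in a row).  The hazard-car task
starts 550 m (~25 s) into the drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ..streams import Event, EventList

__all__ = [
    "ScenarioConfig",
    "kmh_to_ms",
    "distance_to_seconds",
    "generate_gust_events",
    "generate_car_events",
]

CONDITIONS = ("PAD", "Manual")


def kmh_to_ms(v_kmh: float) -> float:
    return v_kmh / 3.6


def distance_to_seconds(distance_m: float, speed_kmh: float) -> float:
    """Travel time for a distance at constant speed (260 m at 80 km/h
    takes 11.7 s)."""
    return distance_m / kmh_to_ms(speed_kmh)


@dataclass
class ScenarioConfig:
    """Scenario parameters of one driving session.

    ``section_s`` exposes a reduced-scale mode: the analysis always splits
    a session into ``n_sections`` equal sections, so desk-scale runs set
    e.g. ``section_s=60`` (6-minute session) instead of the full 600 s.
    """

    duration_s: float = 3600.0
    n_sections: int = 6
    section_s: float | None = None
    speed_kmh: float = 80.0
    gust_spacing_m: tuple[float, float] = (260.0, 330.0)
    gust_speed_kmh: tuple[float, float] = (0.0, 30.0)
    car_spacing_s: tuple[float, float] = (4.0, 6.0)
    unsafe_fraction: tuple[float, float] = (0.12, 0.15)
    car_visible_s: float = 3.5
    hazard_start_m: float = 550.0
    condition: str = "Manual"
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for name in ("gust_spacing_m", "gust_speed_kmh", "car_spacing_s",
                     "unsafe_fraction"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} interval is inverted: [{lo}, {hi}]")
        lo, hi = self.unsafe_fraction
        if lo < 0 or hi > 1:
            raise ValueError("unsafe_fraction must lie within [0, 1]")
        if self.section_s is None:
            if self.duration_s < 600.0:
                raise ValueError(
                    "sessions shorter than 10 min cannot form six full-length "
                    "sections; set section_s explicitly for reduced scale"
                )
            self.section_s = self.duration_s / self.n_sections
        if not np.isclose(self.section_s * self.n_sections, self.duration_s):
            raise ValueError(
                "duration_s must equal n_sections * section_s "
                f"({self.duration_s} != {self.n_sections} * {self.section_s})"
            )

    @property
    def hazard_start_s(self) -> float:
        return distance_to_seconds(self.hazard_start_m, self.speed_kmh)

    def section_of(self, t: float) -> int:
        """0-based section index of a session time (half-open bins)."""
        return min(int(t // self.section_s), self.n_sections - 1)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for k in ("gust_spacing_m", "gust_speed_kmh", "car_spacing_s",
                  "unsafe_fraction"):
            if k in doc and doc[k] is not None:
                doc[k] = tuple(doc[k])
        return cls(**doc)


def generate_gust_events(scenario: ScenarioConfig,
                         rng: np.random.Generator) -> EventList:
    """Wind gusts at uniform 260-330 m spacing, alternating direction,
    uniform 0-30 km/h strength."""
    lo_s = distance_to_seconds(scenario.gust_spacing_m[0], scenario.speed_kmh)
    hi_s = distance_to_seconds(scenario.gust_spacing_m[1], scenario.speed_kmh)
    direction = 1 if rng.random() < 0.5 else -1
    events = []
    t = rng.uniform(lo_s, hi_s)
    while t < scenario.duration_s:
        speed = rng.uniform(*scenario.gust_speed_kmh)
        events.append(Event(t, "gust", {
            "direction": direction,
            "speed_kmh": float(speed),
            "distance_m": float(t * kmh_to_ms(scenario.speed_kmh)),
        }))
        direction = -direction
        t += rng.uniform(lo_s, hi_s)
    return EventList(events)


def _nonadjacent_subset(n: int, u: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample u indices out of n with no two adjacent.

    Bijection: non-adjacent u-subsets of {0..n-1} correspond to plain
    u-subsets of {0..n-u}, via position_i = choice_i + i.
    """
    if u == 0:
        return np.array([], dtype=int)
    choice = np.sort(rng.choice(n - u + 1, size=u, replace=False))
    return choice + np.arange(u)


def generate_car_events(spacing_interval: tuple[float, float],
                        unsafe_fraction: float,
                        duration: float,
                        rng: np.random.Generator,
                        start_time: float = 0.0,
                        fraction_bounds: tuple[float, float] | None = None,
                        ) -> EventList:
    """Parked-car appearances with uniform inter-event gaps and a target
    unsafe fraction, never placing two unsafe cars in a row.

    With ``fraction_bounds`` set, the realized count is clamped so the
    realized fraction stays inside the bounds despite rounding (when the
    sequence is long enough for the bounds to be attainable at all).
    """
    if not 0.0 <= unsafe_fraction <= 0.5:
        raise ValueError(
            "unsafe fractions above 0.5 cannot satisfy the no-two-"
            "consecutive constraint"
        )
    lo, hi = spacing_interval
    times = []
    t = start_time
    while t < duration:
        times.append(t)
        t += rng.uniform(lo, hi)
    n = len(times)
    if n == 0:
        return EventList([])
    u = int(round(unsafe_fraction * n))
    if fraction_bounds is not None:
        u_lo = int(np.ceil(fraction_bounds[0] * n - 1e-9))
        u_hi = int(np.floor(fraction_bounds[1] * n + 1e-9))
        if u_lo <= u_hi:
            u = int(np.clip(u, u_lo, u_hi))
    u = min(u, (n + 1) // 2)
    unsafe_idx = set(_nonadjacent_subset(n, u, rng).tolist())
    events = [
        Event(tt, "car_unsafe" if i in unsafe_idx else "car_safe",
              {"index": i})
        for i, tt in enumerate(times)
    ]
    return EventList(events)


def generate_scenario_events(scenario: ScenarioConfig,
                             rng: np.random.Generator
                             ) -> tuple[EventList, EventList]:
    """(gusts, cars) for one session; the car stream starts at the hazard
    onset and the realized unsafe fraction is drawn from the configured
    interval."""
    gusts = generate_gust_events(scenario, rng)
    frac = rng.uniform(*scenario.unsafe_fraction)
    cars = generate_car_events(scenario.car_spacing_s, frac,
                               scenario.duration_s, rng,
                               start_time=scenario.hazard_start_s,
                               fraction_bounds=scenario.unsafe_fraction)
    return gusts, cars
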