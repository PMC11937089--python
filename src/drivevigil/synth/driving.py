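"""Vehicle lateral dynamics and hazard-task response synthesis.

The lane-keeping model is a deliberately simple second-order plant: wind
gusts apply a lateral acceleration pulse, and either an automated
controller (PAD: stiff, undelayed PD) or a human driver model (Manual:
delayed PD with steering noise whose magnitude grows over the session)
pushes the car back to lane center.  Only the observable consequences are
calibrated — manual lane-keeping RMSE around half a meter that rises with
time on task, and gusts strong enough to displace an uncontrolled car by
more than a meter.
"""

from __future__ import annotations

import numpy as np

from ..streams import ChannelTimeSeries, Event, EventList
from .effects import EffectConfig
from .scenario import ScenarioConfig, kmh_to_ms

__all__ = ["simulate_lateral_dynamics", "generate_presses", "generate_pvt"]

TELEMETRY_RATE = 10.0
TELEMETRY_LABELS = ["lateral_m", "steering_rad", "heading_deg",
                    "velocity_kmh", "distance_m"]

GUST_ACCEL_PER_KMH = 0.012   # m/s^2 of lateral push per km/h of gust speed
GUST_DURATION_S = 3.0
LANE_BOUND_M = 1.75          # |lateral| beyond this counts as a crash

# Manual driver model: delayed proportional-derivative correction.
DRIVER_DELAY_S = 0.3
DRIVER_KP = 1.5              # 1/s^2
DRIVER_KD = 2.0              # 1/s
DRIVER_NOISE_STD = 3.0       # m/s^2 steering-accel noise at section T1
# PAD lane-keeping controller: stiff and undelayed.
PAD_KP = 40.0
PAD_KD = 12.0


def simulate_lateral_dynamics(gusts: EventList,
                              condition: str,
                              scenario: ScenarioConfig,
                              rng: np.random.Generator,
                              effects: EffectConfig | None = None,
                              driver_gain: float = 1.0,
                              ) -> tuple[ChannelTimeSeries, EventList]:
    """Integrate the lateral position under gusts and control.

    Returns 10 Hz driving telemetry (lateral position, steering angle,
    heading, velocity, distance) and the list of crash events (position
    reset to lane center when the lane bound is exceeded).
    """
    if condition not in ("PAD", "Manual"):
        raise ValueError("condition must be 'PAD' or 'Manual'")
    effects = effects or EffectConfig()
    dt = 1.0 / TELEMETRY_RATE
    n = int(round(scenario.duration_s * TELEMETRY_RATE))
    v_ms = kmh_to_ms(scenario.speed_kmh)

    accel = np.zeros(n)
    for e in gusts.of_kind("gust"):
        i0 = int(e.time * TELEMETRY_RATE)
        i1 = min(int((e.time + GUST_DURATION_S) * TELEMETRY_RATE), n)
        accel[i0:i1] += e.payload["direction"] * GUST_ACCEL_PER_KMH * \
            e.payload["speed_kmh"]

    if condition == "PAD":
        kp, kd, delay, noise0 = PAD_KP, PAD_KD, 0, 0.0
    else:
        kp, kd = DRIVER_KP * driver_gain, DRIVER_KD * driver_gain
        delay = int(round(DRIVER_DELAY_S * TELEMETRY_RATE))
        noise0 = DRIVER_NOISE_STD * effects.driver_noise_scale

    # steering noise grows linearly over sections (vigilance decrement)
    sec = np.minimum((np.arange(n) * dt) // scenario.section_s,
                     scenario.n_sections - 1)
    noise_std = noise0 * (1.0 + effects.driver_noise_growth *
                          sec / max(scenario.n_sections - 1, 1))
    noise = rng.standard_normal(n) * noise_std

    x = np.zeros(n)
    vx = np.zeros(n)
    control = np.zeros(n)
    crashes = []
    for i in range(1, n):
        j = max(i - 1 - delay, 0)
        u = -kp * x[j] - kd * vx[j]
        control[i] = u
        ax = accel[i - 1] + u + noise[i - 1]
        vx[i] = vx[i - 1] + ax * dt
        x[i] = x[i - 1] + vx[i] * dt
        if abs(x[i]) > LANE_BOUND_M:
            crashes.append(Event(i * dt, "crash", {"lateral_m": float(x[i])}))
            x[i] = 0.0
            vx[i] = 0.0

    heading = np.degrees(np.arctan2(vx, v_ms))
    steering = control / 25.0    # rough rad-per-(m/s^2) steering ratio
    t = np.arange(n) * dt
    data = np.vstack([
        x, steering, heading,
        np.full(n, scenario.speed_kmh),
        t * v_ms,
    ])
    telem = ChannelTimeSeries(data, TELEMETRY_LABELS, TELEMETRY_RATE,
                              unit="mixed",
                              meta={"condition": condition})
    return telem, EventList(crashes)


def generate_presses(cars: EventList,
                     scenario: ScenarioConfig,
                     effects: EffectConfig,
                     condition: str,
                     rng: np.random.Generator,
                     ) -> tuple[EventList, list[float]]:
    """Button presses responding to unsafe cars.

    Each unsafe car is answered with probability ``hit_prob``; the response
    latency is lognormal around the section's median target (PAD responds
    faster early on).  Returns the press events and the list of true
    latencies actually injected.
    """
    medians = effects.drt_median_targets_s(condition)
    presses = []
    true_drt = []
    for e in cars.of_kind("car_unsafe"):
        if rng.random() > effects.hit_prob:
            continue
        med = medians[scenario.section_of(e.time)]
        drt = float(np.clip(med * np.exp(rng.normal(0.0, effects.drt_sigma_s)),
                            0.25, scenario.car_visible_s - 0.1))
        presses.append(Event(e.time + drt, "press", {"stimulus_index":
                                                     e.payload.get("index")}))
        true_drt.append(drt)
    return EventList(presses), true_drt


def generate_pvt(rng: np.random.Generator,
                 n_stimuli: int = 30,
                 mean_rt_ms: float = 307.0,
                 sd_rt_ms: float = 45.0,
                 lapse_prob: float = 0.02) -> EventList:
    """A short psychomotor-vigilance run: stimuli at random 2-10 s
    intervals, responses at Gaussian latencies, occasional lapses (no
    response within the 1 s window)."""
    events = []
    t = rng.uniform(2.0, 10.0)
    for _ in range(n_stimuli):
        events.append(Event(t, "pvt_stim", {}))
        if rng.random() > lapse_prob:
            rt = float(np.clip(rng.normal(mean_rt_ms, sd_rt_ms), 120.0, 990.0))
            events.append(Event(t + rt / 1000.0, "pvt_resp", {}))
        t += rng.uniform(2.0, 10.0)
    return EventList(events)
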