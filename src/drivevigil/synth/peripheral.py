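"""Synthetic eye-openness and ECG streams.

Eye openness is a plateau at the subject's maximum interrupted by ~0.3 s
blinks and by slow-closure episodes whose duty cycle per 10-min section
matches the configured closure-fraction target (blink closure time is
accounted for when sizing the episodes).  The ECG is a P-QRS-T template
train whose R-R intervals are drawn with the per-section standard
deviation the ground truth prescribes.
"""

from __future__ import annotations

import numpy as np

from ..streams import ChannelTimeSeries
from .effects import EffectConfig
from .scenario import ScenarioConfig

__all__ = ["plan_eye_schedule", "synthesize_eyes", "synthesize_ecg",
           "EYE_RATE", "ECG_RATE"]

EYE_RATE = 600.0
ECG_RATE = 250.0
OPENNESS_MAX = 10.0        # device units
OPENNESS_NOISE = 0.01


def plan_eye_schedule(effects: EffectConfig,
                      scenario: ScenarioConfig,
                      condition: str,
                      rng: np.random.Generator,
                      ) -> dict:
    """Blink times and closure episodes realizing the section targets.

    The mean closure contributed by blinks (Hann-shaped, so half the blink
    duration counts as closed) is subtracted from each section's target
    before slow-closure episodes are sized; the remaining duty cycle is
    split into 2-5 s full-closure episodes at jittered anchors.
    """
    targets = effects.closure_targets(condition)
    blink_duty = effects.blink_rate_per_min / 60.0 * \
        effects.blink_duration_s * 0.5
    n_blinks = rng.poisson(effects.blink_rate_per_min / 60.0 *
                           scenario.duration_s)
    blink_times = np.sort(rng.uniform(0, scenario.duration_s - 0.5, n_blinks))

    episodes: list[tuple[float, float]] = []
    for s in range(scenario.n_sections):
        need = max(targets[s] - blink_duty, 0.0) * scenario.section_s
        if need <= 0:
            continue
        mean_len = 3.5
        k = max(int(np.ceil(need / mean_len)), 1)
        lengths = rng.uniform(2.0, 5.0, k)
        lengths *= need / lengths.sum()
        anchors = (s + (np.arange(k) + rng.uniform(0.2, 0.8, k)) / k) \
            * scenario.section_s
        for a, ln in zip(anchors, lengths):
            t0 = min(max(a, s * scenario.section_s),
                     (s + 1) * scenario.section_s - ln)
            episodes.append((float(t0), float(t0 + ln)))
    return {
        "blink_times": blink_times,
        "episodes": episodes,
        "closure_targets": [float(v) for v in targets],
    }


def synthesize_eyes(effects: EffectConfig,
                    scenario: ScenarioConfig,
                    schedule: dict,
                    rng: np.random.Generator) -> ChannelTimeSeries:
    """600 Hz openness + validity streams for both eyes."""
    fs = EYE_RATE
    n = int(round(scenario.duration_s * fs))
    closure = np.zeros(n)
    for t0, t1 in schedule["episodes"]:
        closure[int(t0 * fs):int(t1 * fs)] = 1.0
    m = max(int(effects.blink_duration_s * fs), 3)
    blink = np.hanning(m)
    for t in schedule["blink_times"]:
        i0 = int(t * fs)
        i1 = min(i0 + m, n)
        closure[i0:i1] = np.maximum(closure[i0:i1], blink[: i1 - i0])

    data = np.empty((4, n))
    for k in range(2):  # left, right
        noise = rng.standard_normal(n) * OPENNESS_NOISE
        data[2 * k] = np.clip(OPENNESS_MAX * (1.0 - closure) + noise,
                              0.0, OPENNESS_MAX * 1.02)
    both_invalid = rng.random(n) < effects.eye_invalid_fraction * 0.6
    for k in range(2):
        extra = rng.random(n) < effects.eye_invalid_fraction * 0.4
        data[2 * k + 1] = (~(both_invalid | extra)).astype(float)
    return ChannelTimeSeries(
        data,
        ["left_openness", "left_valid", "right_openness", "right_valid"],
        fs, unit="device", meta={"condition": scenario.condition},
    )


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def synthesize_ecg(effects: EffectConfig,
                   scenario: ScenarioConfig,
                   condition: str,
                   rng: np.random.Generator,
                   ) -> tuple[ChannelTimeSeries, list[float], np.ndarray]:
    """Template P-QRS-T train with section-scheduled R-R variability.

    Returns (ecg series in mV, per-section target SD in ms, true R-peak
    times).
    """
    fs = ECG_RATE
    n = int(round(scenario.duration_s * fs))
    rr_mean = 60.0 / effects.heart_rate_bpm
    sd_targets = effects.sdrr_targets_ms(condition)

    peaks = []
    t = rng.uniform(0.2, 0.2 + rr_mean)
    while t < scenario.duration_s - 0.3:
        peaks.append(t)
        sd_s = sd_targets[scenario.section_of(t)] / 1000.0
        t += max(rng.normal(rr_mean, sd_s), 0.3)
    peaks = np.array(peaks)

    sig = rng.standard_normal(n) * 0.01   # mV baseline noise
    tt = np.arange(n) / fs
    for tp in peaks:
        i0 = max(int((tp - 0.35) * fs), 0)
        i1 = min(int((tp + 0.45) * fs), n)
        w = tt[i0:i1]
        sig[i0:i1] += (
            1.0 * _gauss(w, tp, 0.012)          # R
            - 0.15 * _gauss(w, tp - 0.045, 0.015)  # Q/S dip
            + 0.12 * _gauss(w, tp - 0.16, 0.025)   # P
            + 0.25 * _gauss(w, tp + 0.25, 0.04)    # T
        )
    ecg = ChannelTimeSeries(sig[None, :], ["ECG"], fs, unit="mV",
                            meta={"condition": condition})
    return ecg, [float(v) for v in sd_targets], peaks
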