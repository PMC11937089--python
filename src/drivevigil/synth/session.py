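"""Assembly of complete synthetic driving sessions."""

from __future__ import annotations

import numpy as np

from ..streams import EventList, MultiStreamSession, mark_data_loss
from .driving import generate_presses, simulate_lateral_dynamics
from .eeg import synthesize_eeg
from .effects import EffectConfig, GroundTruth
from .peripheral import plan_eye_schedule, synthesize_ecg, synthesize_eyes
from .scenario import ScenarioConfig, generate_scenario_events

__all__ = ["generate_session", "stream_rngs"]

_STREAM_NAMES = ("scenario", "driving", "behavior", "eeg", "eyes", "ecg")


def stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One independent generator per stream, spawned from the master seed,
    so changing one stream's parameters never reshuffles the others."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAM_NAMES, children)}


def generate_session(scenario: ScenarioConfig,
                     effects: EffectConfig | None = None,
                     ) -> tuple[MultiStreamSession, GroundTruth]:
    """Generate one condition's full synthetic session.

    The session contains 24-channel cap EEG and 10-channel grid EEG at
    250 Hz, 600 Hz eye openness/validity for both eyes, 250 Hz single-lead
    ECG, 10 Hz driving telemetry and the event stream (cars, presses,
    gusts, crashes), all on one clock starting at 0.  The returned
    GroundTruth records every injected parameter.
    """
    effects = effects or EffectConfig()
    rngs = stream_rngs(scenario.seed)
    condition = scenario.condition

    gusts, cars = generate_scenario_events(scenario, rngs["scenario"])
    telem, crashes = simulate_lateral_dynamics(
        gusts, condition, scenario, rngs["driving"], effects)
    presses, true_drt = generate_presses(
        cars, scenario, effects, condition, rngs["behavior"])

    schedule = plan_eye_schedule(effects, scenario, condition, rngs["eyes"])
    eyes = synthesize_eyes(effects, scenario, schedule, rngs["eyes"])
    cap, grid, band_targets, artifacts, dropouts = synthesize_eeg(
        effects, scenario, condition, rngs["eeg"],
        blink_times=schedule["blink_times"])
    ecg, sdrr_targets, _rpeaks = synthesize_ecg(
        effects, scenario, condition, rngs["ecg"])

    cap = mark_data_loss(cap, dropouts)
    grid = mark_data_loss(grid, dropouts)

    events = EventList(list(gusts) + list(cars) + list(presses) +
                       list(crashes))
    session = MultiStreamSession(
        streams={"eeg_cap": cap, "eeg_grid": grid, "eyes": eyes,
                 "ecg": ecg, "telemetry": telem},
        events=events,
        meta={
            "condition": condition,
            "seed": scenario.seed,
            "duration_s": scenario.duration_s,
            "n_sections": scenario.n_sections,
            "section_s": scenario.section_s,
        },
    )
    truth = GroundTruth(
        condition=condition,
        gusts=gusts, cars=cars, presses=presses, crashes=crashes,
        band_targets_db=band_targets,
        closure_targets=schedule["closure_targets"],
        sdrr_targets_ms=sdrr_targets,
        drt_true_s=true_drt,
        artifact_epochs=artifacts,
        dropouts=[list(d) for d in dropouts],
    )
    return session, truth
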