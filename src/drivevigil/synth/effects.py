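"""Ground-truth effect structure injected into synthetic sessions.

The generator's defaults encode the effect pattern of the motivating
driving study: spectral band power (parietal alpha, frontal beta/theta),
eye closure and R-R variability are all higher under partially automated
driving (PAD) than under manual driving, and all rise over the six 10-min
sections; lane-keeping error grows over time in manual driving, and hazard
response times start faster under PAD and converge to the manual level.

Band levels are in dB re 1 V^2/Hz of band-mean PSD; time profiles are
6-vectors of offsets relative to section T1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ..streams import EventList

__all__ = ["EffectConfig", "GroundTruth", "BANDS_HZ"]

BANDS_HZ: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 26.0),
}


def _default_band_base() -> dict[str, float]:
    # physiological baseline levels (a few uV RMS per band); mode deltas
    # and time profiles carry the vigilance effects of interest
    return {"alpha": -118.25, "beta": -117.43, "theta": -110.03}


def _default_mode_delta() -> dict[str, float]:
    return {"alpha": 1.24, "beta": 1.18, "theta": 0.55}


def _default_time_profile() -> dict[str, list[float]]:
    return {
        "alpha": [0.0, 0.68, 1.05, 1.12, 1.18, 1.33],
        "beta": [0.0, 0.30, 0.61, 0.50, 0.48, 0.65],
        "theta": [0.0, 0.50, 0.83, 0.87, 0.94, 1.09],
    }


@dataclass
class EffectConfig:
    """Injected effect parameters with known ground truth.

    Per-band entries use keys ``alpha``/``beta``/``theta``; ``*_profile``
    vectors hold the T1-relative offset of each of the six sections.
    """

    band_base_db: dict[str, float] = field(default_factory=_default_band_base)
    band_mode_delta_db: dict[str, float] = field(default_factory=_default_mode_delta)
    band_time_profile_db: dict[str, list[float]] = field(default_factory=_default_time_profile)
    band_cell_noise_db: float = 0.4

    perclos_base: float = 0.019
    perclos_mode_delta: float = 0.05
    perclos_time_profile: list[float] = field(
        default_factory=lambda: [0.0, 0.007, 0.010, 0.012, 0.017, 0.015])
    blink_rate_per_min: float = 6.0
    blink_duration_s: float = 0.3
    eye_invalid_fraction: float = 0.005

    sdrr_base_ms: float = 162.6
    sdrr_time_profile_ms: list[float] = field(
        default_factory=lambda: [0.0, 10.0, 18.0, 25.0, 39.4, 30.3])
    heart_rate_bpm: float = 72.0

    drt_median_s: float = 0.95
    drt_sigma_s: float = 0.25
    drt_pad_profile_s: list[float] = field(
        default_factory=lambda: [-0.15, -0.10, 0.0, 0.0, 0.02, 0.05])
    hit_prob: float = 0.988

    driver_noise_growth: float = 0.25   # fractional rise of steering noise T1->T6
    driver_noise_scale: float = 1.0     # subject-level steering-noise multiplier

    artifact_rate_per_hour: float = 2.0
    artifact_amp_uv: float = 500.0
    artifact_duration_s: float = 0.3
    dropout_rate_per_hour: float = 3.0
    dropout_duration_s: tuple[float, float] = (0.2, 1.0)

    def __post_init__(self):
        if not 0.0 <= self.hit_prob <= 1.0:
            raise ValueError("hit_prob must lie in [0, 1]")
        for s, p in enumerate(self.perclos_time_profile):
            c = self.perclos_base + self.perclos_mode_delta + p
            if not 0.0 <= self.perclos_base + p <= 1.0 or not 0.0 <= c <= 1.0:
                raise ValueError(
                    f"closure target outside [0, 1] in section {s + 1}"
                )
        for band, prof in self.band_time_profile_db.items():
            if len(prof) != 6:
                raise ValueError(f"{band} time profile must have 6 entries")

    # --- realized per-section targets ------------------------------------
    def band_targets_db(self, band: str, condition: str) -> np.ndarray:
        """Six per-section band-power targets (dB) for one condition."""
        base = self.band_base_db[band]
        delta = self.band_mode_delta_db[band] if condition == "PAD" else 0.0
        return base + delta + np.asarray(self.band_time_profile_db[band])

    def closure_targets(self, condition: str) -> np.ndarray:
        delta = self.perclos_mode_delta if condition == "PAD" else 0.0
        return self.perclos_base + delta + np.asarray(self.perclos_time_profile)

    def sdrr_targets_ms(self, condition: str) -> np.ndarray:
        # same R-R variability schedule in both conditions by default
        return self.sdrr_base_ms + np.asarray(self.sdrr_time_profile_ms)

    def drt_median_targets_s(self, condition: str) -> np.ndarray:
        off = (np.asarray(self.drt_pad_profile_s) if condition == "PAD"
               else np.zeros(len(self.drt_pad_profile_s)))
        return self.drt_median_s + off

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["dropout_duration_s"] = list(self.dropout_duration_s)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "dropout_duration_s" in doc:
            doc["dropout_duration_s"] = tuple(doc["dropout_duration_s"])
        return cls(**doc)


@dataclass
class GroundTruth:
    """Everything a recovery test needs to know about one generated session."""

    condition: str
    gusts: EventList
    cars: EventList
    presses: EventList
    crashes: EventList
    band_targets_db: dict[str, list[float]] = field(default_factory=dict)
    closure_targets: list[float] = field(default_factory=list)
    sdrr_targets_ms: list[float] = field(default_factory=list)
    drt_true_s: list[float] = field(default_factory=list)
    artifact_epochs: list[dict] = field(default_factory=list)
    dropouts: list[list[float]] = field(default_factory=list)

    def __post_init__(self):
        for lst in (self.gusts, self.cars, self.presses):
            t = lst.times()
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("ground-truth event times must be strictly increasing")
        kinds = [e.kind for e in self.cars]
        for a, b in zip(kinds, kinds[1:]):
            if a == b == "car_unsafe":
                raise ValueError("two consecutive unsafe cars in ground truth")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "condition": self.condition,
            "gusts": self.gusts.to_frame().to_dict("records"),
            "cars": self.cars.to_frame().to_dict("records"),
            "presses": self.presses.to_frame().to_dict("records"),
            "crashes": self.crashes.to_frame().to_dict("records"),
            "band_targets_db": {k: list(map(float, v))
                                for k, v in self.band_targets_db.items()},
            "closure_targets": list(map(float, self.closure_targets)),
            "sdrr_targets_ms": list(map(float, self.sdrr_targets_ms)),
            "drt_true_s": list(map(float, self.drt_true_s)),
            "artifact_epochs": self.artifact_epochs,
            "dropouts": [list(map(float, d)) for d in self.dropouts],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        import pandas as pd

        doc = json.loads(Path(path).read_text())

        def evl(key):
            recs = doc[key]
            if not recs:
                return EventList([])
            return EventList.from_frame(pd.DataFrame(recs))

        return cls(
            condition=doc["condition"],
            gusts=evl("gusts"), cars=evl("cars"),
            presses=evl("presses"), crashes=evl("crashes"),
            band_targets_db=doc["band_targets_db"],
            closure_targets=doc["closure_targets"],
            sdrr_targets_ms=doc["sdrr_targets_ms"],
            drt_true_s=doc["drt_true_s"],
            artifact_epochs=doc["artifact_epochs"],
            dropouts=[tuple(d) for d in doc["dropouts"]],
        )
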