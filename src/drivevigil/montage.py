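"""Electrode montages: 24-channel cap, 10-channel around-ear grid, and the
virtual-channel map that approximates 10-20 scalp positions from grid
channel differences.

Positions are rough 2-D head coordinates (x toward the right ear, y toward
the nasion, unit head radius) — enough for neighbor finding and
distance-weighted interpolation; no forward modeling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .streams import ChannelTimeSeries

__all__ = [
    "CAP_LABELS",
    "GRID_LABELS",
    "CAP_POSITIONS",
    "GRID_POSITIONS",
    "VirtualChannelMap",
    "default_virtual_map",
    "load_montage",
    "save_montage",
]

# 10-20 cap, 24 ring electrodes incl. both mastoids.
CAP_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "Fz": (0.0, 0.50), "F8": (0.81, 0.59),
    "FC1": (-0.31, 0.27), "FC2": (0.31, 0.27),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.73, -0.29), "CP1": (-0.27, -0.27), "CPz": (0.0, -0.25),
    "CP2": (0.27, -0.27), "CP6": (0.73, -0.29),
    "P3": (-0.50, -0.52), "Pz": (0.0, -0.50), "P4": (0.50, -0.52),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "M1": (-1.05, -0.35), "M2": (1.05, -0.35),
}
CAP_LABELS: list[str] = list(CAP_POSITIONS)

# Around-the-right-ear grid: frontal, central, parietal and occipital
# pick-ups, periocular electrodes for EOG, mastoid reference and ground.
GRID_POSITIONS: dict[str, tuple[float, float]] = {
    "G_FP": (0.45, 0.92),    # forehead, low and frontal
    "G_C": (0.78, 0.05),     # above the ear, toward C4
    "G_P": (0.90, -0.40),    # behind the ear, toward P4
    "G_O": (0.55, -0.85),    # low occipital
    "G_EOG_L": (0.20, 0.88),  # inner canthus side
    "G_EOG_R": (0.62, 0.80),  # outer canthus side
    "G_EOG_U": (0.42, 0.98),  # above the eye
    "G_EOG_D": (0.45, 0.70),  # below the eye
    "G_M2": (1.05, -0.35),   # right mastoid (reference)
    "G_DRL": (1.10, -0.15),  # driven-right-leg ground
}
GRID_LABELS: list[str] = list(GRID_POSITIONS)


@dataclass
class VirtualChannelMap:
    """Linear combinations of grid channels approximating 10-20 locations.

    Each virtual channel is ``sum(coefficient * source)``; the default map
    takes the nearest grid electrode minus the grid mastoid reference, plus
    horizontal/vertical/diagonal EOG pairs.  Coefficients are configurable
    metadata; the map holds no data.
    """

    combos: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    reference: str = "G_M2"

    def __post_init__(self):
        for name, sources in self.combos.items():
            if len(sources) < 2:
                raise ValueError(
                    f"virtual channel {name!r} must reference >= 2 sources"
                )

    def validate(self, available: list[str]) -> None:
        for name, sources in self.combos.items():
            for src, _ in sources:
                if src not in available:
                    raise KeyError(
                        f"virtual channel {name!r} needs source {src!r} "
                        f"which is not in the grid montage"
                    )

    def apply(self, grid: ChannelTimeSeries) -> ChannelTimeSeries:
        """Derive the virtual channels from a grid recording."""
        self.validate(grid.labels)
        rows = []
        for name, sources in self.combos.items():
            x = np.zeros(grid.n_samples)
            for src, coef in sources:
                x += coef * grid.data[grid.labels.index(src)]
            rows.append(x)
        out = ChannelTimeSeries(
            np.array(rows), list(self.combos), grid.rate, grid.start_time,
            grid.unit, list(grid.loss_mask), dict(grid.meta),
        )
        out.meta["virtual"] = True
        return out


def default_virtual_map() -> VirtualChannelMap:
    return VirtualChannelMap(
        combos={
            "FPz_M2": [("G_FP", 1.0), ("G_M2", -1.0)],
            "C4_M2": [("G_C", 1.0), ("G_M2", -1.0)],
            "P4_M2": [("G_P", 1.0), ("G_M2", -1.0)],
            "O2_M2": [("G_O", 1.0), ("G_M2", -1.0)],
            "EOGh": [("G_EOG_L", 1.0), ("G_EOG_R", -1.0)],
            "EOGv": [("G_EOG_U", 1.0), ("G_EOG_D", -1.0)],
            "EOGd": [("G_EOG_U", 1.0), ("G_EOG_R", -1.0)],
        },
        reference="G_M2",
    )


def save_montage(path: str | Path,
                 vmap: VirtualChannelMap | None = None) -> None:
    vmap = vmap or default_virtual_map()
    doc = {
        "cap": {k: list(v) for k, v in CAP_POSITIONS.items()},
        "grid": {k: list(v) for k, v in GRID_POSITIONS.items()},
        "virtual": {
            "reference": vmap.reference,
            "combos": {
                name: [[src, coef] for src, coef in sources]
                for name, sources in vmap.combos.items()
            },
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_montage(path: str | Path):
    """Return (cap_positions, grid_positions, VirtualChannelMap)."""
    doc = yaml.safe_load(Path(path).read_text())
    cap = {k: tuple(v) for k, v in doc["cap"].items()}
    grid = {k: tuple(v) for k, v in doc["grid"].items()}
    vmap = VirtualChannelMap(
        combos={
            name: [(src, float(coef)) for src, coef in sources]
            for name, sources in doc["virtual"]["combos"].items()
        },
        reference=doc["virtual"]["reference"],
    )
    return cap, grid, vmap
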