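"""Synthetic cohorts for parameter-recovery and calibration studies.

Two granularities are provided.  ``sample_feature_table`` draws tidy
subject x condition x section feature tables directly from the effect
model (subject baseline offsets, subject-specific effect jitter, cell
noise) — the right tool for large replicate counts such as null
calibration of the statistics tree.  ``simulate_cohort_sessions`` runs
the full signal-level generator per subject and condition, for end-to-end
pipeline recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effects import EffectConfig
from .scenario import ScenarioConfig
from .session import generate_session

__all__ = ["CohortConfig", "sample_feature_table", "sample_subject_effects",
           "simulate_cohort_sessions", "sample_questionnaires"]


@dataclass
class CohortConfig:
    """Between- and within-subject variability of the synthetic cohort."""

    n_subjects: int = 28
    subject_sd: float = 1.5          # baseline offset SD (feature units)
    subject_mode_sd: float = 0.3     # subject-specific mode-delta jitter
    subject_slope_scale_sd: float = 0.2  # lognormal sigma on the time profile
    cell_sd: float = 0.4             # residual per-cell noise

    # questionnaire / PVT population parameters
    tlx_manual_mean: float = 8.16
    tlx_pad_mean: float = 6.98
    tlx_sd: float = 2.2
    sss_means: dict = field(default_factory=lambda: {
        "baseline": 2.61, "PAD": 4.71, "Manual": 4.29})
    sss_sd: float = 1.0
    pvt_means_ms: dict = field(default_factory=lambda: {
        "baseline": 307.12, "after_first": 323.2, "after_second": 323.57})
    pvt_between_sd_ms: float = 40.0
    pvt_within_sd_ms: float = 12.0


def sample_feature_table(base: float,
                         mode_delta: float,
                         time_profile,
                         cohort: CohortConfig,
                         rng: np.random.Generator,
                         feature: str = "feature",
                         modes: tuple[str, str] = ("PAD", "Manual"),
                         ) -> pd.DataFrame:
    """Draw one tidy feature table from the additive effect model.

    value = base + subject offset
          + (mode_delta + subject jitter) * [mode == PAD]
          + profile[section] * subject slope scale
          + cell noise.

    With ``mode_delta = 0`` and a zero profile this is an exact null.
    """
    profile = np.asarray(time_profile, float)
    k = len(profile)
    rows = []
    for s in range(cohort.n_subjects):
        off = rng.normal(0.0, cohort.subject_sd)
        dj = mode_delta + rng.normal(0.0, cohort.subject_mode_sd)
        slope_scale = np.exp(rng.normal(0.0, cohort.subject_slope_scale_sd))
        for mode in modes:
            for j in range(k):
                val = base + off + (dj if mode == "PAD" else 0.0) \
                    + profile[j] * slope_scale \
                    + rng.normal(0.0, cohort.cell_sd)
                rows.append({"subject": f"S{s + 1:02d}", "condition": mode,
                             "section": j + 1, "value": val,
                             "feature": feature})
    return pd.DataFrame(rows)


def sample_subject_effects(effects: EffectConfig,
                           cohort: CohortConfig,
                           rng: np.random.Generator) -> EffectConfig:
    """Per-subject effect parameters: jittered baselines, mode deltas and
    time-profile scale, shared across that subject's two conditions.

    A latent subject factor couples the EEG baseline shift with the
    driver's steering-noise level, so less vigilant synthetic subjects
    show both higher band power and worse lane keeping (the study's
    EEG-vs-RMSE correlation structure in miniature).
    """
    z = rng.standard_normal()
    rho = 0.7
    base = {b: v + cohort.subject_sd * (rho * z +
                                        np.sqrt(1 - rho ** 2) *
                                        rng.standard_normal())
            for b, v in effects.band_base_db.items()}
    delta = {b: v + rng.normal(0.0, cohort.subject_mode_sd)
             for b, v in effects.band_mode_delta_db.items()}
    scale = np.exp(rng.normal(0.0, cohort.subject_slope_scale_sd))
    profile = {b: [p * scale for p in prof]
               for b, prof in effects.band_time_profile_db.items()}
    perclos_base = float(np.clip(
        effects.perclos_base * np.exp(rng.normal(0.0, 0.3)), 0.0, 0.5))
    sdrr_base = effects.sdrr_base_ms * np.exp(rng.normal(0.0, 0.15))
    drt_median = effects.drt_median_s * np.exp(rng.normal(0.0, 0.15))
    hr = float(np.clip(effects.heart_rate_bpm + rng.normal(0.0, 6.0),
                       45.0, 110.0))
    return replace(
        effects,
        band_base_db=base,
        band_mode_delta_db=delta,
        band_time_profile_db=profile,
        perclos_base=perclos_base,
        sdrr_base_ms=float(sdrr_base),
        drt_median_s=float(drt_median),
        heart_rate_bpm=hr,
        driver_noise_scale=float(np.exp(0.2 * z)),
    )


def simulate_cohort_sessions(cohort: CohortConfig,
                             effects: EffectConfig,
                             scenario: ScenarioConfig,
                             seed: int):
    """Yield (subject_id, condition, session, ground_truth) for a full
    cohort; condition order is counterbalanced across subjects."""
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(cohort.n_subjects * 4)
    rng = np.random.default_rng(ss.spawn(1)[0])
    for s in range(cohort.n_subjects):
        subject = f"S{s + 1:02d}"
        subj_effects = sample_subject_effects(effects, cohort, rng)
        order = ["PAD", "Manual"] if s % 2 == 0 else ["Manual", "PAD"]
        for c, condition in enumerate(order):
            sc = replace(scenario, condition=condition,
                         seed=int(subj_seeds[2 * s + c] % (2 ** 31)))
            session, truth = generate_session(sc, subj_effects)
            session.meta["subject"] = subject
            session.meta["order_index"] = c
            yield subject, condition, session, truth


def sample_questionnaires(cohort: CohortConfig,
                          rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Synthetic NASA-TLX subscales, SSS ratings and PVT means."""
    tlx_rows, sss_rows, pvt_rows = [], [], []
    for s in range(cohort.n_subjects):
        subject = f"S{s + 1:02d}"
        off = rng.normal(0.0, cohort.tlx_sd * 0.7)
        for mode, mean in (("Manual", cohort.tlx_manual_mean),
                           ("PAD", cohort.tlx_pad_mean)):
            subs = np.clip(mean + off +
                           rng.normal(0.0, cohort.tlx_sd * 0.7, 6), 0, 20)
            tlx_rows.append({"subject": subject, "condition": mode,
                             **{f"subscale_{i + 1}": float(v)
                                for i, v in enumerate(subs)},
                             "score": float(subs.mean())})
        soff = rng.normal(0.0, cohort.sss_sd * 0.6)
        for phase, mean in cohort.sss_means.items():
            v = np.clip(round(mean + soff +
                              rng.normal(0.0, cohort.sss_sd * 0.8)), 1, 7)
            sss_rows.append({"subject": subject, "phase": phase,
                             "score": int(v)})
        poff = rng.normal(0.0, cohort.pvt_between_sd_ms)
        for phase, mean in cohort.pvt_means_ms.items():
            pvt_rows.append({"subject": subject, "phase": phase,
                             "mean_rt_ms": float(mean + poff +
                                                 rng.normal(0.0, cohort.pvt_within_sd_ms))})
    return {"nasa_tlx": pd.DataFrame(tlx_rows),
            "sss": pd.DataFrame(sss_rows),
            "pvt": pd.DataFrame(pvt_rows)}
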