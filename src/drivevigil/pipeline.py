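"""End-to-end feature extraction and analysis orchestration.

``clean_eeg`` runs the full EEG chain (bandpass, bad channels, mastoid
reference, virtual grid channels, merge, second bandpass, ASR);
``extract_session_features`` turns one session into per-section feature
rows for every modality it finds; ``extract_cohort`` and
``analyze_cohort`` chain generation, extraction and the statistics tree.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, peripheral, spectral
from .eeg_clean import (clean_merged, derive_virtual_channels,
                        detect_bad_channels, fir_bandpass,
                        interpolate_bad_channels, reref_mastoids)
from .stats import StatReport, analyze_feature, feature_correlations
from .streams import ChannelTimeSeries, MultiStreamSession, merge_streams, resample
from .synth import (CohortConfig, EffectConfig, ScenarioConfig,
                    sample_questionnaires, simulate_cohort_sessions)

__all__ = ["clean_eeg", "extract_session_features", "extract_cohort",
           "analyze_cohort", "run_all"]

log = logging.getLogger("drivevigil")

#: channels actually consumed by the band-power analysis
ANALYSIS_CHANNELS = ["P4", "Fz", "P4_M2", "FPz_M2", "O2_M2"]


def clean_eeg(cap: ChannelTimeSeries, grid: ChannelTimeSeries,
              asr_cutoff_k: float = 20.0) -> ChannelTimeSeries:
    """Full cleaning chain from raw cap + grid to an analysis-ready merge.

    Both systems are bandpassed 0.1-40 Hz and brought to 250 Hz; cap bad
    channels are interpolated (mastoids exempt) and the cap is referenced
    to averaged mastoids (the mastoid rows are then dropped); virtual
    10-20 channels are derived from the grid; the merged data get a
    1-40 Hz pass and ASR.
    """
    cap = fir_bandpass(cap, 0.1, 40.0)
    grid = fir_bandpass(grid, 0.1, 40.0)
    if not np.isclose(cap.rate, 250.0):
        cap = resample(cap, 250.0)
    if not np.isclose(grid.rate, 250.0):
        grid = resample(grid, 250.0)

    scalp = cap.pick([l for l in cap.labels if l not in ("M1", "M2")])
    try:
        bads = detect_bad_channels(scalp)
    except ValueError:
        bads = set()
    if bads:
        log.info("interpolating bad cap channels: %s", sorted(bads))
        cap = interpolate_bad_channels(cap, bads)
    cap = reref_mastoids(cap)
    cap = cap.pick([l for l in cap.labels if l not in ("M1", "M2")])

    virt = derive_virtual_channels(grid)
    merged = merge_streams(cap, virt)
    return clean_merged(merged, cutoff_k=asr_cutoff_k)


def _eeg_band_rows(session: MultiStreamSession) -> pd.DataFrame:
    duration = session.meta["duration_s"]
    n_sections = session.meta.get("n_sections", 6)
    cleaned = clean_eeg(session.streams["eeg_cap"], session.streams["eeg_grid"])
    cleaned = cleaned.pick([c for c in ANALYSIS_CHANNELS
                            if c in cleaned.labels])
    eps = spectral.epoch(cleaned, 10.0)
    eps = spectral.reject_epochs(eps, cleaned.loss_mask)
    spsd = spectral.sectioned_psd(eps, duration, n_sections)
    frames = []
    for band in spectral.BANDS.values():
        for system in ("cap", "grid"):
            ch = band.channel(system)
            if ch not in spsd.labels:
                log.warning("channel %s missing; %s/%s dropped", ch,
                            band.name, system)
                continue
            df = spectral.band_power_sections(spsd, band, ch)
            df["system"] = system
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def extract_session_features(session: MultiStreamSession,
                             features: tuple[str, ...] = (
                                 "eeg", "perclos", "hrv", "rmse", "drt"),
                             perclos_window_s: float = 60.0,
                             hrv_window_s: float = 60.0,
                             ecg_prominence: float = 0.5,
                             ) -> dict[str, pd.DataFrame]:
    """Per-section feature tables for one session.

    Missing streams degrade gracefully: the corresponding feature is
    reported as missing rather than failing the whole extraction.
    """
    duration = session.meta["duration_s"]
    n_sections = session.meta.get("n_sections", 6)
    out: dict[str, pd.DataFrame] = {}

    if "eeg" in features:
        if {"eeg_cap", "eeg_grid"} <= set(session.streams):
            out["eeg_bands"] = _eeg_band_rows(session)
        else:
            log.warning("EEG streams missing; band power skipped")

    if "perclos" in features:
        if "eyes" in session.streams:
            series = peripheral.perclos(session.streams["eyes"],
                                        window_s=perclos_window_s)
            pm = peripheral.section_means(series, duration, n_sections,
                                          value_col="perclos")
            out["perclos"] = pm.rename(columns={"value": "perclos_pct"})
        else:
            log.warning("eye stream missing; PERCLOS skipped")

    if "hrv" in features:
        if "ecg" in session.streams:
            rr = peripheral.detect_rpeaks(session.streams["ecg"],
                                          prominence=ecg_prominence)
            out["hrv"] = peripheral.hrv_sections(rr, duration, n_sections,
                                                 window_s=hrv_window_s)
        else:
            log.warning("ECG stream missing; HRV skipped")

    if "rmse" in features:
        if "telemetry" in session.streams:
            out["rmse"] = behavior.rmse_lane(session.streams["telemetry"],
                                             duration, n_sections)
        else:
            log.warning("telemetry missing; lane RMSE skipped")

    if "drt" in features:
        cars = session.events.of_kind("car_safe", "car_unsafe")
        presses = session.events.of_kind("press")
        if len(cars):
            records = behavior.match_responses(cars, presses)
            out["drt"] = behavior.drt_sections(records, duration, n_sections)
            out["drt"].attrs["accuracy_pct"] = \
                behavior.detection_accuracy(records)
        else:
            log.warning("no car events; hazard-task features skipped")
    return out


def _tidy(df: pd.DataFrame, subject: str, condition: str,
          value_col: str) -> pd.DataFrame:
    t = df[["section"]].copy()
    t["subject"] = subject
    t["condition"] = condition
    t["value"] = df[value_col]
    return t


def extract_cohort(cohort: CohortConfig,
                   effects: EffectConfig,
                   scenario: ScenarioConfig,
                   seed: int,
                   features: tuple[str, ...] = ("eeg",),
                   ) -> dict[str, pd.DataFrame]:
    """Generate + extract a whole cohort into tidy feature tables.

    Keys are e.g. ``alpha/cap``, ``perclos``, ``rmse``; values are tidy
    subject/condition/section/value tables ready for ``analyze_feature``.
    """
    perclos_w = min(60.0, scenario.section_s)
    hrv_w = min(60.0, scenario.section_s)
    acc: dict[str, list[pd.DataFrame]] = {}
    accuracy_rows = []
    for subject, condition, session, _truth in simulate_cohort_sessions(
            cohort, effects, scenario, seed):
        feats = extract_session_features(
            session, features, perclos_window_s=perclos_w, hrv_window_s=hrv_w)
        if "eeg_bands" in feats:
            for (band, system), grp in feats["eeg_bands"].groupby(
                    ["band", "system"]):
                acc.setdefault(f"{band}/{system}", []).append(
                    _tidy(grp, subject, condition, "value_db"))
        if "perclos" in feats:
            acc.setdefault("perclos", []).append(
                _tidy(feats["perclos"], subject, condition, "perclos_pct"))
        if "hrv" in feats:
            acc.setdefault("sdrr", []).append(
                _tidy(feats["hrv"], subject, condition, "sdrr_ms"))
        if "rmse" in feats and condition == "Manual":
            acc.setdefault("rmse", []).append(
                _tidy(feats["rmse"], subject, condition, "rmse_m"))
        if "drt" in feats:
            acc.setdefault("drt", []).append(
                _tidy(feats["drt"], subject, condition, "drt_s"))
            accuracy_rows.append({"subject": subject, "condition": condition,
                                  "accuracy_pct":
                                  feats["drt"].attrs["accuracy_pct"]})
    tables = {k: pd.concat(v, ignore_index=True) for k, v in acc.items()}
    if accuracy_rows:
        tables["accuracy"] = pd.DataFrame(accuracy_rows)
    return tables


def analyze_cohort(tables: dict[str, pd.DataFrame]) -> dict[str, StatReport]:
    """Run the statistics tree on every sectioned feature table."""
    reports = {}
    for name, table in tables.items():
        if not {"subject", "condition", "section", "value"} <= set(table.columns):
            continue
        try:
            reports[name] = analyze_feature(table, feature=name)
        except ValueError as err:
            log.warning("analysis of %s failed: %s", name, err)
    return reports


def run_all(cohort: CohortConfig, effects: EffectConfig,
            scenario: ScenarioConfig, seed: int,
            out_dir: str | Path | None = None,
            features: tuple[str, ...] = ("eeg", "perclos", "hrv",
                                         "rmse", "drt"),
            ) -> dict:
    """Simulate, extract, analyze; optionally write everything to disk.

    Returns ``{"tables": ..., "reports": ..., "questionnaires": ...,
    "correlations": ...}`` and, with ``out_dir`` set, writes tidy CSVs
    plus JSON stat reports.
    """
    tables = extract_cohort(cohort, effects, scenario, seed, features)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    quest = sample_questionnaires(cohort, rng)
    reports = analyze_cohort(tables)

    corr = None
    if "rmse" in tables:
        for band in ("alpha", "beta", "theta"):
            key = f"{band}/grid"
            if key in tables:
                c = feature_correlations(
                    tables[key][tables[key]["condition"] == "Manual"],
                    tables["rmse"])
                c.insert(0, "band", band)
                corr = c if corr is None else pd.concat([corr, c],
                                                        ignore_index=True)
    result = {"tables": tables, "reports": reports,
              "questionnaires": quest, "correlations": corr}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"feature_{name.replace('/', '_')}.csv",
                         index=False)
        for name, q in quest.items():
            q.to_csv(out / f"questionnaire_{name}.csv", index=False)
        for name, rep in reports.items():
            rep.to_json(out / f"stats_{name.replace('/', '_')}.json")
        if corr is not None:
            corr.to_csv(out / "correlations.csv", index=False)
    return result
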