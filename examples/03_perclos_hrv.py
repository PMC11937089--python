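"""PERCLOS and heart-rate variability from one full-length session's
peripheral streams.

PERCLOS: percentage of eye closure (1 - openness / max openness, averaged
over valid eyes) in a 60 s window sliding by 1 s.  HRV: R-peaks from the
ECG by prominence-gated peak finding, SDRR = sample SD of R-R intervals
per 1-min window, then section means.
"""

import numpy as np

from drivevigil.peripheral import (detect_rpeaks, hrv_sections, perclos,
                                   section_means)
from drivevigil.synth import (EffectConfig, ScenarioConfig,
                              plan_eye_schedule, synthesize_ecg,
                              synthesize_eyes)

effects = EffectConfig()
scenario = ScenarioConfig(duration_s=3600.0, condition="PAD", seed=3)
rng = np.random.default_rng(3)

schedule = plan_eye_schedule(effects, scenario, "PAD", rng)
eyes = synthesize_eyes(effects, scenario, schedule, rng)
series = perclos(eyes)                       # one value per second
sec = section_means(series, 3600.0, 6, value_col="perclos")
print("PERCLOS % per section:", sec["value"].round(2).tolist())
print("injected closure %  :",
      [round(100 * c, 2) for c in schedule["closure_targets"]])

ecg, sd_targets, _ = synthesize_ecg(effects, scenario, "PAD", rng)
rr = detect_rpeaks(ecg, prominence=0.5)
hrv = hrv_sections(rr, 3600.0, 6)
print("\nSDRR ms per section :", hrv["sdrr_ms"].round(1).tolist())
print("injected SDRR ms    :", [round(v, 1) for v in sd_targets])
print("mean heart rate     :", round(hrv['bpm'].mean(), 1), "bpm")
# Both PERCLOS and SDRR rise over sections: drowsiness accumulating with
# time on task, more so under partial automation.
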