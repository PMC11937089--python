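"""Driving-performance and hazard-task features of one session.

Lane-keeping RMSE (deviation about lane center) per section for manual
driving, discrimination response times (DRT) to unsafely parked cars,
detection accuracy, plus the PVT and NASA-TLX scoring helpers.
"""

import numpy as np

from drivevigil.behavior import (detection_accuracy, drt_sections,
                                 match_responses, nasa_tlx_score, pvt_score,
                                 rmse_lane)
from drivevigil.synth import (EffectConfig, ScenarioConfig, generate_pvt,
                              generate_session)

scenario = ScenarioConfig(duration_s=3600.0, condition="Manual", seed=4)
session, truth = generate_session(scenario, EffectConfig())

telem = session.streams["telemetry"]
print("lane RMSE (m) per 10-min section:",
      rmse_lane(telem, 3600.0)["rmse_m"].round(3).tolist())
print("(manual lane keeping degrades with time on task)")

cars = session.events.of_kind("car_safe", "car_unsafe")
records = match_responses(cars, session.events.of_kind("press"))
print("\nhazard detection accuracy: "
      f"{detection_accuracy(records):.1f} % of unsafe cars answered")
print("mean DRT (s) per section:",
      drt_sections(records, 3600.0)["drt_s"].round(2).tolist())

pvt = generate_pvt(np.random.default_rng(4))
mean_ms, n = pvt_score(pvt.times("pvt_stim"), pvt.times("pvt_resp"))
print(f"\nPVT: mean RT {mean_ms:.0f} ms over {n} valid responses")
print("NASA-TLX overall of [10, 8, 6, 9, 7, 8]:",
      nasa_tlx_score([10, 8, 6, 9, 7, 8]))
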