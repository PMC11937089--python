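"""Generate one synthetic driving session and look at what is inside.

A session bundles cap + grid EEG (250 Hz), eye openness (600 Hz), ECG
(250 Hz), driving telemetry (10 Hz) and the scenario's event stream on a
shared clock.  We use the reduced desk scale (six 60 s sections instead
of six 10 min ones); every downstream stage is scale-agnostic.
"""

from drivevigil.synth import EffectConfig, ScenarioConfig, generate_session

scenario = ScenarioConfig(duration_s=360.0, section_s=60.0,
                          condition="Manual", seed=1)
session, truth = generate_session(scenario, EffectConfig())

print("streams:")
for name, s in session.streams.items():
    print(f"  {name:10s} {s.n_channels:3d} ch x {s.n_samples:7d} samples "
          f"@ {s.rate:g} Hz [{s.unit}]")

cars = session.events.of_kind("car_safe", "car_unsafe")
unsafe = session.events.of_kind("car_unsafe")
print(f"\nhazard cars: {len(cars)} total, {len(unsafe)} unsafe "
      f"({100 * len(unsafe) / len(cars):.1f} % — scenario draws 12-15 %)")
print(f"wind gusts: {len(session.events.of_kind('gust'))} "
      "(alternating direction, 260-330 m apart)")
print(f"button presses: {len(session.events.of_kind('press'))}")

print("\ninjected per-section alpha targets (dB re 1 V^2/Hz):")
print("  ", [round(v, 2) for v in truth.band_targets_db["alpha"]])
print("injected closure fractions:",
      [round(c, 3) for c in truth.closure_targets])
# The targets rise over sections: that is the simulated vigilance decrement.
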