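"""Simulate a tagged deployment and recover its prey captures.

Generates one synthetic deployment with known capture dives, runs dive
detection, phase partitioning and kinematic features, classifies click
trains by inter-click interval, calibrates capture thresholds on the
acoustically confirmed dives, and compares the classified captures to the
simulation's ground truth.
"""

import orcaforage as of

cfg = of.SimulationConfig(seed=11, duration_h=1.0, sampling_rate=10.0,
                          dive_rate=15.0, capture_rate=5.0)
dep = of.simulate_deployment(cfg)
print(f"simulated {dep.record.duration_h:.1f} h at {cfg.sampling_rate:.0f} Hz: "
      f"{len(dep.truth['dive_intervals'])} dives, "
      f"{len(dep.truth['capture_ids'])} true capture dives")

dives = of.analyze_dives(dep.series)
print(f"detector found {len(dives)} dives "
      f"(max depth {max(d.max_depth for d in dives):.0f} m)")

clicks = of.classify_clicks([e.time for e in dep.events if e.kind == "click"])
events = clicks + [e for e in dep.events if e.kind == "handling"]
summaries = of.summarize_dive_acoustics(dives, events)
print(f"searching time (slow-click-only dives): "
      f"{of.searching_time(dives, summaries):.2f} h")

confirmed = of.confirmed_captures(dives, summaries)
thresholds = of.calibrate_from_dives(dives, confirmed, "NRKW")
print(f"calibrated on {thresholds.n_confirmed} buzz+handling dives: "
      f"jerk >= {thresholds.jerk_min:.0f} x median, "
      f"roll >= {thresholds.roll_min:.0f} deg, "
      f"heading variance >= {thresholds.headvar_min:.2f} "
      f"(sensitivity {thresholds.tpr:.0%}, FPR {thresholds.fpr:.0%})")

predicted = sorted(d.dive_id for d in dives if of.classify_dive(d, thresholds))
print(f"classified capture dives: {predicted}")
print(f"ground-truth capture dives: {sorted(dep.truth['capture_ids'])}")
print("The kinematic filter recovers the capture dives the acoustics could")
print("confirm and, by construction, never misses a confirmed capture.")
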