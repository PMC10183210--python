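"""Cohort summaries from the packaged deployment table.

Computes per-deployment prey-capture rates from the tabulated counts and
durations, then group means by population and sex, the demographic
subgroup means, and the headline percent differences between groups.
"""

import orcaforage as of

records = of.load_deployment_fixture()
report = of.validate_cohort(records)
print(f"{report.n_records} deployments, {report.total_hours:.1f} h total "
      f"({report.hours_by_population['NRKW']:.1f} h NRKW, "
      f"{report.hours_by_population['SRKW']:.1f} h SRKW)")

metrics = of.metrics_from_table(records)

print("\nMean prey-capture rate (capture dives per hour of deployment):")
means = {}
for g in of.group_means(metrics, records, "population_sex", "capture_rate"):
    means[g.key] = g.mean
    se = f" +/- {g.se:.2f}" if g.se is not None else ""
    print(f"  {g.key[0]} {g.key[1]}: {g.mean:.2f}{se}  (n={g.n})")

print("\nMean foraging efficiency (capture dives per hour of searching):")
for g in of.group_means(metrics, records, "population_sex", "efficiency"):
    print(f"  {g.key[0]} {g.key[1]}: {g.mean:.2f}  (n={g.n})")

print("\nAdult females by calf status / adult males by mother status:")
for grouping in ("calf_status", "mother_status"):
    for g in of.group_means(metrics, records, grouping):
        print(f"  {g.key}: {g.mean:.2f} captures/h  (n={g.n})")

nf_nm = of.percent_difference(means[("NRKW", "F")], means[("NRKW", "M")])
sm_sf = of.percent_difference(means[("SRKW", "M")], means[("SRKW", "F")])
print(f"\nNRKW females capture {nf_nm:.0f}% more prey per hour than NRKW males;")
print(f"SRKW males capture {sm_sf:.0f}% more prey per hour than SRKW females --")
print("opposite sex biases in the two populations.")
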