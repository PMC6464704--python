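"""Viability normalization and group statistics for an excitotoxicity assay.

Simulates a plate-reader experiment (wells per condition, multiplicative
noise), expresses each condition as percent of the vehicle-control mean,
and compares conditions by one-way ANOVA with Tukey post-hoc tests.
"""

import synaptodev as sd

params = sd.PlateSimParams(
    conditions=("vehicle", "NMDA_10uM", "NMDA_100uM", "NMDA_300uM"),
    true_viability={"vehicle": 1.0, "NMDA_10uM": 0.93, "NMDA_100uM": 0.65, "NMDA_300uM": 0.40},
    vehicle_mean=1000.0, cv=0.05, n_wells=6, seed=7,
)
table, truth = sd.gen_plate(params)
res = sd.normalize_viability(table)
print("viability as % of vehicle (mean ± s.e.m.):")
for _, row in res["summary"].iterrows():
    print(f"  {row['condition']:>11}: {row['mean']:6.1f} ± {row['sem']:4.1f}  (n={row['n']})")

groups = res["per_well"].rename(columns={"viability_pct": "value"})
stats = sd.compare_groups(groups, test="anova_tukey")
print(f"\none-way ANOVA: F = {stats['statistic']:.1f}, p = {stats['p']:.2e}")
print("Tukey pairwise comparisons:")
print(stats["pairwise"].to_string(index=False))

# APEGS palmitoylation ratio for one immunoblot lane: two PEG-shifted bands
# (palmitoylated pools) over the band matched to the -HA control, per actin.
lane = sd.LaneDensitometry(shifted_bands=[0.3, 0.2], nonpalm_band=0.25, actin=2.0)
print("\nAPEGS lane ratio:", sd.apegs_ratio(lane))
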