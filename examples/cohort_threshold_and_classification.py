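"""Derive the ischemia cutoff and classify a synthetic cohort.

Simulates a per-vessel cohort (104 patients; territory MBF 274 +/- 62 without
obstructive stenosis, 165 +/- 61 with CAD-RADS >= 3, diffuse 130 +/- 35 in
microvascular-disease patients), derives the optimal stress-MBF cutoff by
bootstrap ROC / mean Youden index restricted to unequivocal territories
(CAD-RADS 0 vs 4), then applies the discordance classifier.
"""

from ccperf import (CohortConfig, bootstrap_youden_threshold, cohort_summary,
                    simulate_cohort)

table = simulate_cohort(CohortConfig(n_patients=104, seed=1))
print(f"cohort: {table.patient_id.nunique()} patients, "
      f"{len(table)} territories")

res = bootstrap_youden_threshold(table, n_boot=1000, seed=1)
print(f"optimal stress MBF cutoff {res.threshold:.1f} mL/min/100g "
      f"(95% CI {res.ci_low:.1f}-{res.ci_high:.1f}, {res.n_boot} bootstraps)")

summary = cohort_summary(table, threshold=200.0)
print("per-patient labels:")
print(summary["patients"].label.value_counts().to_string())
rec = summary["mvd_recovery"]
print(f"MVD truth recovery: sensitivity {rec['sensitivity']:.2f}, "
      f"specificity {rec['specificity']:.2f}")
obst = summary["territory_means"]["obstructed_nondiabetic"]
non = summary["territory_means"]["non_obstructed_nondiabetic"]
print(f"non-diabetic territory MBF: obstructed {obst[0]:.0f} +/- {obst[1]:.0f},"
      f" non-obstructed {non[0]:.0f} +/- {non[1]:.0f} mL/min/100g")
rho, p = summary["spearman_mbf_vs_cadrads"]
print(f"Spearman rho (MBF vs CAD-RADS, non-diabetics) {rho:.2f} (p={p:.2g})")
print("Low MBF concentrates in obstructed territories; diabetic patients")
print("with diffusely low flow and no obstructive vessel surface as")
print("mvd_diffuse, the microvascular-disease pattern.")
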