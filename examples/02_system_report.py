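"""Covariate-adjusted system profiles and the group-comparison report.

Builds system profiles for one contrast, removes age/sex effects by pooled
regression, and runs the permutation report: control effects vs zero,
patient deviation (normative Z) tests, and the direct FLE-vs-TLE
comparison, all with Benjamini-Hochberg FDR across systems.
"""

from taskgrad import (
    adjust_covariates, group_contrast_report, simulate_cohort, system_means,
)

cohort = simulate_cohort(seed=4)
roster = cohort.roster
prof = system_means(cohort.betas["verbal_wm"].values, cohort.atlas)
adj = prof.copy()
adj[:] = adjust_covariates(prof.to_numpy(), roster[["age", "sex"]].to_numpy(float))

groups = {g: adj[(roster["group"] == g).to_numpy()] for g in ("CTR", "FLE", "TLE")}
report = group_contrast_report(groups, mode="systems", n_perm=2000, seed=1)

dev = report[report["comparison"] == "FLE_deviation"]
print(dev[["unit", "mean_z", "statistic", "p_perm", "p_fdr", "sig_fdr"]]
      .to_string(index=False))
print("\nmean_z is the average normative deviation of FLE patients from the")
print("control distribution; negative values at dorsal attention / control")
print("reflect the injected loss of task-positive activation, the positive")
print("default-mode value its reduced deactivation.  sig_fdr flags systems")
print("surviving FDR correction at q = 0.05; at ~56 patients per group a")
print("chance deviation can also reach significance (limbic here), which is")
print("why the study-level claims rest on the calibration and recovery")
print("experiments, not single cohorts.")
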