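"""Exploratory correlation and factor analysis of a simulated cohort.

Runs the battery for 60 listeners, computes the Spearman correlation
matrix of the outcome table, and contrasts the mean absolute correlation
within the low-frequency and high-frequency variable clusters against
the correlation between them — the two-cluster structure the cohort
generator builds in through its two latent severities.  Parallel
analysis then selects the number of factors and a maximum-likelihood +
varimax solution is extracted.
"""

import itertools

import numpy as np

from bearsim.analysis import (
    factor_analysis_ml, parallel_analysis, spearman_matrix,
)
from bearsim.battery import BatteryConfig, run_cohort_study
from bearsim.observers import CohortConfig, make_cohort

cohort = make_cohort(CohortConfig(n_listeners=60, seed=7))
table, _ = run_cohort_study(cohort, BatteryConfig(master_seed=13))

rho, sig = spearman_matrix(table)
lf = ["AUD_LF", "HTL_LF", "DynR_LF", "Slope_LF", "SRT_Q"]
hf = ["AUD_HF", "HTL_HF", "DynR_HF", "Slope_HF", "SRT_N", "SMR_HF", "TMR_HF"]
within = np.mean([abs(rho.loc[a, b]) for grp in (lf, hf)
                  for a, b in itertools.combinations(grp, 2)])
between = np.mean([abs(rho.loc[a, b]) for a in lf for b in hf])
print(f"mean |rho| within LF/HF clusters: {within:.2f}")
print(f"mean |rho| between clusters:      {between:.2f}")
binaural = ["IPD_fmax", "BP_20", "BMR"]
print("binaural outcomes vs HF audiogram:",
      {v: round(rho.loc[v, "AUD_HF"], 2) for v in binaural})

cols = [c for c in rho.columns if table[c].notna().mean() >= 0.7]
data = table[cols].dropna()
k = parallel_analysis(data, seed=3)
print(f"\nparallel analysis: {k} factors ({len(data)} listeners, "
      f"{len(cols)} variables)")
report = factor_analysis_ml(table[cols], max(k, 2))
print("variance explained per factor (%):",
      [round(v, 1) for v in report.variance_explained])
for factor in report.loadings.columns:
    salient = report.salient()[factor].dropna()
    print(f"  {factor}: " + ", ".join(
        f"{v} ({salient[v]:+.2f})" for v in salient.index))
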