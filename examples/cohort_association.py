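"""Cohort-level association of cluster-type heterogeneity with recurrence.

Simulates a 21-specimen cohort whose recurrence hazard quadruples for
heterogeneous tumors (two or more cluster types), quantifies every
specimen through the image pipeline, dichotomizes the type fractions by
ROC, and tests heterogeneity against recurrence (χ²) plus Cox / ρ² per
quantification.
"""

import pandas as pd

from glycoclust.pipeline import cohort_statistics, quantify_specimen
from glycoclust.synthetic import SimulationParams, simulate_cohort

params = SimulationParams(n_specimens=21, seed=10)
bundle = simulate_cohort(params)
rows = [quantify_specimen(s.specimen_id, s.channels)[0].as_row() for s in bundle.specimens]
result = cohort_statistics(pd.DataFrame(rows), bundle.outcomes)

t = result.het_chi2.table
print(f"heterogeneous vs recurrence table: [[{t[0,0]},{t[0,1]}],[{t[1,0]},{t[1,1]}]]")
print(f"chi2 = {result.het_chi2.statistic:.2f}, p = {result.het_chi2.p:.4f}")
print()
print(result.survival[["quantification", "logrank_p", "cox_beta", "rho2_xoq"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
truth = bundle.outcomes.set_index("specimen_id")["het_truth"] >= 2
called = result.quant.set_index("specimen_id")["heterogeneous"]
agree = (called == truth.loc[called.index]).mean()
print(f"measured heterogeneity matches construction truth for {agree:.0%} of specimens")
print()
print("the chi2 row tests the dichotomized >= 2-cluster-type call against")
print("observed recurrence; rho2_xoq is the explained randomness of each")
print("continuous quantification in a Cox model (n_types is usually highest,")
print("mirroring the value of combining cluster types).")
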