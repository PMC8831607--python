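"""Genomic inflation factor and QQ coordinates for a null burden scan.

Runs the LOF pipeline on a 300-gene null cohort (no implanted
enrichment) and computes the genomic inflation factor lambda plus
QQ-plot coordinates with 95% order-statistic envelopes.
"""

import numpy as np

import exocollapse as xc

cfg = xc.SimulationConfig(n_genes=300, seed=12)
cohort = xc.simulate_cohort(cfg)
model = xc.get_model("lof")
qual = xc.qualifying_sets(cohort.callset, cohort.records, model)
results = xc.collapse_and_test(qual, cohort.callset, model,
                               xc.thresholds(300, 7),
                               gene_universe=sorted(
                                   set(cohort.annotations.gene)))
pvals = np.array([r.p_two_sided for r in results])

res = xc.qq_with_bands(pvals)
above = np.mean(res.qq_points[:, 1] > res.band_upper)
below = np.mean(res.qq_points[:, 1] < res.band_lower)
print(f"genes tested:          {len(pvals)}")
print(f"lambda:                {res.lambda_gc:.3f}")
print(f"fraction p < 0.05:     {np.mean(pvals < 0.05):.3f}")
print(f"points above envelope: {100 * above:.1f}%  (inflation side)")
print(f"points below envelope: {100 * below:.1f}%  (conservative side)")

top = results[0]
print(f"top gene: {top.gene}  {top.case_carriers}/{top.cases_total} vs "
      f"{top.control_carriers}/{top.controls_total}  "
      f"p = {top.p_two_sided:.1e}  genome-wide: {top.genome_wide_flag}")

# xc.plot_qq(res, "qq.png")   # uncomment to render the figure

print("\nWhat to look for on a null cohort: lambda near 1 (slightly"
      "\nbelow -- exact-test p-values are discrete and stochastically"
      "\nlarge under the null, which also pushes bulk points below the"
      "\nlower envelope), essentially no points above the upper envelope,"
      "\nand a calibrated p < 0.05 fraction. Excess points ABOVE the"
      "\nenvelope would indicate inflation from confounding. Note the top"
      "\ngene here: a pure sampling fluctuation (a control-side excess)"
      "\ncrosses the Bonferroni bar, which is loose at only 300 genes"
      "\n(0.05/300 = 1.7e-4) -- exactly why exome scans correct for the"
      "\nfull ~18,653-gene universe rather than the genes they happen to"
      "\ntest.")
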