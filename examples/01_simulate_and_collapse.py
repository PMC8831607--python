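"""Simulate a small case/control cohort and run a gene-burden scan.

Builds a synthetic annotated exome slice (100 cases, 1,000 controls, 40
genes) with one gene enriched for rare loss-of-function carriers in
cases, then runs the full pipeline: coverage harmonization, qualifying-
variant selection under the LOF model, per-gene carrier collapsing, and
the two-tailed Fisher exact scan with Bonferroni thresholds.
"""

import exocollapse as xc

cfg = xc.SimulationConfig(
    n_cases=100, n_controls=1000, n_genes=40, variants_per_gene=30,
    enrichments=[xc.Enrichment("GENE00007", case_carrier_freq=0.30,
                               control_carrier_freq=0.08)],
    seed=1,
)
cohort = xc.simulate_cohort(cfg)

harm = xc.harmonize_sites(cohort.callset)
callset = cohort.callset.subset_variants(harm.retained)
records = [cohort.records[j] for j in harm.retained]

model = xc.get_model("lof")
qual = xc.qualifying_sets(callset, records, model)
spec = xc.thresholds(n_genes=40, n_models=7)
results = xc.collapse_and_test(qual, callset, model, spec,
                               gene_universe=sorted(
                                   set(cohort.annotations.gene)))

print(f"{len(results)} genes tested; "
      f"genome-wide alpha = {spec.alpha_genome:.2e}\n")
print("gene        cases     controls  p          OR     flag")
for r in results[:5]:
    orr = f"{r.odds_ratio:.2f}" if r.odds_ratio else "  -  "
    flag = "genome-wide" if r.genome_wide_flag else ""
    print(f"{r.gene}  {r.case_carriers:3d}/{r.cases_total}   "
          f"{r.control_carriers:4d}/{r.controls_total}  "
          f"{r.p_two_sided:.3e}  {orr}  {flag}")
print("\nThe implanted gene should rank first with an odds ratio near the"
      "\nimplanted contrast (0.30 vs 0.08 carrier frequency, OR ~ 4.9);"
      "\nthe remaining genes are null and should show p-values spread"
      "\nroughly uniformly.")
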