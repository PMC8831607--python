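"""Coverage harmonization: excluding sites with case/control depth bias.

Sequencing depth that differs systematically between cases and controls
fabricates carrier-count differences.  The harmonization step tests, per
site, whether the number of adequately covered samples is independent of
case/control status (two-sided binomial test against the pooled covered
fraction) and drops sites reaching p <= 0.01.
"""

import exocollapse as xc

# an empty 849/15,640 cohort with 40 sites, fully covered
fx = xc.make_fixture_from_counts(0, 849, 0, 15640, n_variants=40)

# knock out coverage at 15 sites: cases covered 85% of the time,
# controls 99% -- a realistic capture-kit disparity
cs = xc.simulate_coverage_imbalance(fx.callset, n_sites=15,
                                    case_cover_frac=0.85,
                                    control_cover_frac=0.99, seed=2)
res = xc.harmonize_sites(cs, alpha=0.01)
print(f"{cs.n_variants} sites, {len(res.excluded)} excluded at "
      f"alpha = {res.alpha}")
for j, vid, p in res.excluded[:5]:
    cov_case, cov_ctrl = cs.covered_counts()
    print(f"  site {vid}: covered {cov_case[j]}/849 cases vs "
          f"{cov_ctrl[j]}/15640 controls, p = {p:.2e}")

print("\nAll 15 imbalanced sites should be excluded (an 85%-vs-99%"
      "\ncoverage gap at these cohort sizes is overwhelming evidence of"
      "\ndependence), while the 25 fully covered sites are retained.")
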