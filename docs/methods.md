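# Methods

## Pipeline overview

The analysis consumes a multi-sample genotype matrix (VCF), a per-variant
annotation table (effect class, per-population reference allele frequencies,
PolyPhen-2 HumVar label, TraP score, site QC metrics), per-sample QC metrics,
and per-site coverage indicators. Processing order:

1. **Sample gates** — exclude samples with contamination > 8% or with ≤ 87%
   of the consensus coding sequence (CCDS) covered at 10×; prune relatives
   (up to third degree) so only mutually unrelated samples remain.
2. **Variant QC** — a pure conjunction of site/genotype thresholds
   (quality ≥ 30, quality-by-depth ≥ 2, genotype quality ≥ 20, read-position
   rank-sum ≥ −3, mapping quality ≥ 40, mapping-quality rank-sum > −10,
   depth ≥ 10, Fisher strand bias ≤ 60 for SNVs / ≤ 200 for indels, het
   alternate-allele ratio ≥ 25%, no external failure flag).
3. **Coverage harmonization** — per site, a two-sided binomial test of
   independence between coverage and case/control status; sites with
   p ≤ 0.01 are removed before any burden counting.
4. **Qualifying-variant selection** under a named model; **collapsing** to
   per-gene distinct-carrier counts; **two-tailed Fisher exact test** per
   gene against Bonferroni thresholds.
5. **Inflation diagnostics** (λ, QQ coordinates with order-statistic bands).

## Statistical choices

**Two-sided convention.** The exact test is two-sided by minimum-likelihood
summation: p is the total probability of all tables with the observed margins
whose hypergeometric point probability does not exceed the observed table's.
This is the convention of standard implementations (the computation is
delegated to `scipy.stats.fisher_exact`; the test suite checks it against
exhaustive integer-exact enumeration for every table with total ≤ 60, and
against exact big-integer enumeration at cohort scale).

**Odds ratios.** Default is the cross-product (a·d)/(b·c) with a Woolf logit
confidence interval; the conditional maximum-likelihood estimate (noncentral
hypergeometric; `scipy.stats.contingency.odds_ratio`) with its exact interval
is available as `method="cmle"`. For large, well-filled tables the two agree
to ~2 decimals; where a published value sits between them (e.g. 4.04 vs 4.05
on the 19/849-vs-88/15,640 table) the CMLE reproduces the printed rounding.
The estimate is reported as absent when a zero cell (sample) or a structural
boundary (CMLE) leaves it undefined.

**Coverage-test null.** The tested cohort's covered count is compared to
Binomial(n, p̂) with p̂ the pooled covered fraction of both cohorts — the
standard pooled-proportion formulation of an independence test when only
counts are available. Which cohort is tested is configurable (`tested=`);
swapping the cohorts *and* the tested side is a pure relabeling and gives the
identical p, but the decision can differ across tested sides for very
asymmetric cohort sizes, which is why the side is exposed as configuration.

**Relatedness pruning.** Within each kinship component the retained set is an
exact maximum independent set (branch-and-bound, deterministic
lexicographic tie-break), so the pruned cohort is as large as possible while
containing no related pair; a greedy fallback guards against pathological
components larger than 28 samples. Kinship components in real cohorts are
nearly always families of < 10.

**MAF semantics.** The frequency ceiling applies to the *folded* (minor)
allele frequency and must hold in every configured reference population and
in both sequencing cohorts (case and control allele frequencies computed from
post-QC genotypes). A missing reference-population frequency counts as 0
(absence from a reference panel is not evidence of commonness); a variant
missing a predictor annotation that the model requires is conservatively
non-qualifying with reason `"unannotated"`. The common-LOF complement uses
the complementary rule — the folded MAF exceeds the ceiling in *at least one*
population or cohort — so the rare model and its complement exactly partition
the frequency-unconstrained LOF set.

**Recessive carriers.** A sample carries under the recessive model if it is
alt-homozygous for one qualifying variant or heterozygous for two or more
distinct qualifying variants in the gene (putative compound heterozygote; no
phase check is attempted).

**λ definition.** λ = median(χ²₁-quantiles of 1−p) / 0.454936. Genes with
p = 1 are included by default; `exclude_ones=True` drops them (zero-carrier
genes and modal tables), which recenters λ near 1 for discrete tests — both
modes are reported in the diagnostics because the choice materially shifts λ.
QQ expected values use the i/(n+1) plotting position; envelopes are
Beta(i, n−i+1) quantiles at 0.025/0.975.

## The synthetic-cohort generator

The generator emulates the *statistical* structure the collapsing analysis
assumes, not the biology of any particular exome:

- Default cohort 849 cases / 15,640 controls; 2,000 genes; variant count per
  gene Poisson(110); effect classes apportioned deterministically
  (largest-remainder) with weights 0.16 stop-gained, 0.13 frameshift, 0.055 +
  0.055 canonical splice, 0.35 missense, 0.18 synonymous, 0.07 splice-region.
- Rare-variant allele frequencies draw from 0.0045·Beta(2.5, 1); 10% of
  variants are ultra-rare (af ≤ 10⁻⁴, substrate for the MAF ≤ 0.01% models);
  ~0.3 common variants per gene (af uniform on [0.02, 0.2]) feed the
  common-LOF complement. Per-population reference frequencies jitter the
  global value by LogNormal(0, 0.05).
- Null genotypes are i.i.d. across all samples (per variant: het with
  probability 2·af·(1−af), alt-hom with af²), so non-enriched genes have
  equal expected carrier frequency in cases and controls by construction.
- Implanted enrichments draw per-sample carrier indicators
  Bernoulli(case-frequency) / Bernoulli(control-frequency); each implanted
  carrier receives exactly one qualifying variant, spread round-robin over
  enough distinct variant sites that every site's realized cohort allele
  frequency stays below the 1% ceiling. Background variants of an enriched
  gene are generated as benign missense so the implanted contrast is the
  gene's entire qualifying signal.
- Site QC metrics draw from passing-heavy distributions (~2% of variants fail
  at least one rule), and per-sample metrics default to passing values;
  missing genotypes are emitted at a configurable rate (default 0).
- All draws flow from one seeded `numpy` generator; the seed is recorded in
  the callset metadata and a content hash makes reproducibility checkable.

**Calibration of the defaults.** The defaults put the per-gene rare-LOF
qualifying carrier frequency around 15–20% — roughly an order of magnitude
above typical real-exome sparsity. This is deliberate. With 849 cases, the
minimum-likelihood exact test has a point mass at p = 1 (the modal table)
of ≈ 0.03 *regardless* of carrier frequency, and at realistic carrier counts
the mass is far larger; since λ is a median statistic, those atoms deflate it
well below 1 (we measure λ ≈ 0.4–0.7 at realistic sparsity). A median-based
inflation diagnostic over 2,000 genes is only informative when the null
p-value distribution is near-continuous, so the generator targets that
regime; the residual atom still centers λ at ≈ 0.92 with seed-to-seed spread
± ~0.05 (the irreducible noise of a median over 2,000 genes). Expect
λ ≈ 0.85–1.02 on null cohorts; values materially above 1 indicate genuine
inflation, and the conservative side is a property of exact tests, not
miscalibration — the synonymous-control behavior of published collapsing
studies (λ just below 1) shows the same signature.

**What the generator does not emulate** — and what passing tests therefore do
not show about real data: linkage disequilibrium and haplotype structure
(except the explicit phased fixtures of the haplotype module), population
stratification and ancestry-correlated allele frequencies, capture-kit batch
structure beyond the single coverage-imbalance mechanism, genotyping error
correlated with depth, per-gene length/constraint variation, and realistic
per-gene variant-density spectra. Conclusions about robustness to those
phenomena require real cohorts.

## Numerical and degenerate-input choices

- Empty 2×2 tables return p = 1; p is clamped to (0, 1] by construction.
- Gene results sort by ascending p with ties broken by gene symbol, so output
  order is deterministic.
- Samples with missing genotypes at every qualifying site of a gene still
  count in the denominators (cohort sizes are fixed by design).
- A genotype at an uncovered site is a contract violation (`validate_coverage`);
  the simulator's coverage knockout sets such genotypes to missing.
- Haplotype grouping seeds groups with fully observed carrier haplotypes
  (processed in input order); a partially observed haplotype joins the unique
  compatible group, is inconclusive when compatible with several, and founds
  a new group when compatible with none. Grouping is invariant to sample
  order; by default flanking identity is evaluated over informative sites
  only (sites carrying the alternate allele in at least one haplotype).
- CpG-transition classification requires the three-base reference-strand
  context; strand symmetry (C>T with 3′ G ↔ G>A with 5′ C) is exact.

## Test-suite design

Unit oracles are independent of the implementation: exact integer
hypergeometric enumeration (math.comb / int64 Pascal triangle) for the exact
test, exact rational binomial enumeration for the coverage test, brute-force
maximum-independent-set search for kinship pruning, and naive genotype
rescans for carrier counts. Statistical properties run at reduced problem
sizes chosen to keep the suite within a few minutes — 2,000 genes for null
calibration (the full published universe is 18,653), 100 replicates for
odds-ratio recovery, 150–300 genes for calibration spot checks — with
acceptance bands derived by Monte Carlo at those sizes before freezing.

## Known limitations

- The exact test's discreteness makes genome-wide false-positive counts
  conservative but λ biased low (see calibration above); λ comparisons
  across models are meaningful, absolute comparisons to 1 need care.
- The coverage-harmonization test conditions on the pooled rate estimated
  from the same data (an approximate independence test); at α = 0.01 the
  realized null exclusion rate is near but not exactly 1%.
- The recessive model's compound-het rule does not use phase; two variants on
  the same haplotype count as a carrier (matching the no-phase-check design).
- PolyPhen-2, TraP, contamination, kinship and ancestry values are consumed
  as annotations; computing them is out of scope.
- The CLI reads whole VCFs into memory; cohorts beyond ~10⁷ genotype calls
  should use the library's sparse in-memory path (the simulator's native
  output) rather than VCF round trips.
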