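"""Per-gene carrier collapsing and the exome-wide Fisher exact burden scan.

Each gene reduces to a 2x2 carrier table

    =============  ==========  =============
                   carrier     non-carrier
    =============  ==========  =============
    cases          a           n1 - a
    controls       c           n2 - c
    =============  ==========  =============

tested with the two-tailed Fisher exact test (minimum-likelihood
summation over the hypergeometric family with fixed margins). Bonferroni
thresholds divide alpha = 0.05 by the gene universe size (genome-wide)
and additionally by the number of correction-counted models (study-wide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .callset import CallSet
from .models import QualifyingModel


def _validate_cells(*cells):
    for x in cells:
        if isinstance(x, (bool, np.bool_)):
            raise TypeError("table cells must be integers, got bool")
        if isinstance(x, float) or isinstance(x, np.floating):
            if not float(x).is_integer():
                raise ValueError(f"non-integer table cell {x}")
        elif not isinstance(x, (int, np.integer)):
            raise TypeError(f"table cells must be integers, got {type(x)}")
        if x < 0:
            raise ValueError(f"negative table cell {x}")
    return [int(x) for x in cells]


def fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness follows the minimum-likelihood convention: the p-value
    sums every hypergeometric point probability (margins fixed) that does
    not exceed the observed table's.
    """
    a, b, c, d = _validate_cells(a, b, c, d)
    if a + b + c + d == 0:
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def odds_ratio(a, b, c, d, method: str = "sample") -> float | None:
    """Odds ratio of the 2x2 table; ``None`` when undefined.

    ``"sample"`` is the cross-product (a*d)/(b*c), undefined when b*c = 0.
    ``"cmle"`` is the conditional maximum-likelihood estimate under the
    noncentral hypergeometric model, undefined (infinite or zero with a
    structural boundary) when a marginal cell pins the table.
    """
    a, b, c, d = _validate_cells(a, b, c, d)
    if method == "sample":
        if b * c == 0:
            return None
        return (a * d) / (b * c)
    if method == "cmle":
        if min(a + b, c + d, a + c, b + d) == 0:
            return None
        est = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional").statistic
        if not math.isfinite(est):
            return None
        return float(est)
    raise ValueError(f"unknown odds-ratio method {method!r}")


def odds_ratio_ci(a, b, c, d, method: str = "sample",
                  alpha: float = 0.05) -> tuple[float, float] | None:
    """Confidence interval for the odds ratio.

    ``"sample"`` uses the Woolf logit interval (undefined with any zero
    cell); ``"cmle"`` uses the exact conditional interval.
    """
    a, b, c, d = _validate_cells(a, b, c, d)
    if method == "sample":
        if 0 in (a, b, c, d):
            return None
        log_or = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return math.exp(log_or - z * se), math.exp(log_or + z * se)
    if method == "cmle":
        if min(a + b, c + d, a + c, b + d) == 0:
            return None
        ci = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional"
                               ).confidence_interval(1 - alpha)
        return float(ci.low), float(ci.high)
    raise ValueError(f"unknown odds-ratio method {method!r}")


@dataclass(frozen=True)
class ThresholdSpec:
    """Bonferroni thresholds for G genes and M correction-counted models."""

    n_genes: int
    n_models: int

    def __post_init__(self):
        if self.n_genes < 1 or self.n_models < 1:
            raise ValueError("G and M must be >= 1")

    @property
    def alpha_genome(self) -> float:
        return 0.05 / self.n_genes

    @property
    def alpha_study(self) -> float:
        return 0.05 / (self.n_models * self.n_genes)


def thresholds(n_genes: int, n_models: int) -> ThresholdSpec:
    return ThresholdSpec(n_genes, n_models)


@dataclass(frozen=True)
class BurdenResult:
    """Per-gene (or per-variant) carrier table with test results."""

    gene: str
    case_carriers: int
    cases_total: int
    control_carriers: int
    controls_total: int
    p_two_sided: float
    odds_ratio: float | None
    genome_wide_flag: bool = False
    study_wide_flag: bool = False

    @property
    def case_freq(self) -> float:
        return self.case_carriers / self.cases_total

    @property
    def control_freq(self) -> float:
        return self.control_carriers / self.controls_total

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.case_carriers, self.cases_total - self.case_carriers,
                self.control_carriers,
                self.controls_total - self.control_carriers)


def burden_from_counts(gene: str, a: int, n1: int, c: int, n2: int,
                       spec: ThresholdSpec | None = None,
                       or_method: str = "sample") -> BurdenResult:
    """Build one BurdenResult from carrier counts."""
    if not 0 <= a <= n1 or not 0 <= c <= n2:
        raise ValueError("carrier counts outside cohort sizes")
    p = fisher_two_sided(a, n1 - a, c, n2 - c)
    orr = odds_ratio(a, n1 - a, c, n2 - c, method=or_method)
    return BurdenResult(
        gene=gene, case_carriers=a, cases_total=n1,
        control_carriers=c, controls_total=n2,
        p_two_sided=p, odds_ratio=orr,
        genome_wide_flag=spec is not None and p < spec.alpha_genome,
        study_wide_flag=spec is not None and p < spec.alpha_study,
    )


def _call_arrays(qualifying_calls, callset: CallSet):
    """(samples, variants, genotypes) arrays from a call collection."""
    samples = getattr(qualifying_calls, "samples", None)
    if samples is not None:
        return (qualifying_calls.samples, qualifying_calls.variants,
                qualifying_calls.genotypes)
    pairs = sorted(qualifying_calls)
    if not pairs:
        return (np.empty(0, dtype=np.int64),) * 2 + (
            np.empty(0, dtype=np.int8),)
    n_s, n_v = callset.genotypes.shape
    for i, j in pairs:
        if not (0 <= i < n_s and 0 <= j < n_v):
            raise ValueError(f"call ({i}, {j}) outside the cohort matrix")
    s = np.array([p[0] for p in pairs], dtype=np.int64)
    v = np.array([p[1] for p in pairs], dtype=np.int64)
    g = np.array([callset.genotypes[i, j] for i, j in pairs], dtype=np.int8)
    return s, v, g


def carrier_indices(qualifying_calls, callset: CallSet,
                    zygosity: str = "dominant") -> set[int]:
    """Distinct carrier sample indices for one gene's qualifying calls.

    Dominant: any het or alt-hom qualifying call makes a carrier.
    Recessive: alt-hom at one qualifying variant, or het at two or more
    distinct qualifying variants (putative compound heterozygote; phase
    is not checked).
    """
    samples, variants, gts = _call_arrays(qualifying_calls, callset)
    if zygosity == "dominant":
        return set(np.unique(samples).tolist())
    if zygosity != "recessive":
        raise ValueError(f"unknown zygosity {zygosity!r}")
    carriers = set(np.unique(samples[gts == 2]).tolist())
    het = gts == 1
    if het.any():
        # distinct het variants per sample
        pair_keys = np.unique(np.stack([samples[het], variants[het]], axis=1),
                              axis=0)
        s_ids, n_vars = np.unique(pair_keys[:, 0], return_counts=True)
        carriers.update(s_ids[n_vars >= 2].tolist())
    return carriers


def collapse_and_test(qualifying: dict[str, set], callset: CallSet,
                      model: QualifyingModel, spec: ThresholdSpec,
                      gene_universe=None, or_method: str = "sample",
                      ) -> list[BurdenResult]:
    """Collapse qualifying calls per gene and run the exome-wide FET scan.

    Genes in ``gene_universe`` (default: the genes present in
    ``qualifying``) with no qualifying variant are reported with zero
    carriers and p = 1. Results are sorted by ascending p, ties broken by
    gene symbol.
    """
    n1, n2 = callset.n_cases, callset.n_controls
    case_idx = set(np.flatnonzero(callset.is_case))
    n_samples = callset.n_samples
    universe = sorted(gene_universe) if gene_universe is not None \
        else sorted(qualifying)
    missing = set(qualifying) - set(universe)
    if gene_universe is not None and missing:
        raise ValueError(
            f"qualifying genes outside the gene universe: {sorted(missing)[:5]}")
    results = []
    for gene in universe:
        calls = qualifying.get(gene, set())
        samples, _, _ = _call_arrays(calls, callset)
        if samples.size and (samples.min() < 0
                             or samples.max() >= n_samples):
            raise ValueError(
                f"sample index outside cohort in gene {gene}")
        carriers = carrier_indices(calls, callset, model.zygosity)
        a = len(carriers & case_idx)
        c = len(carriers) - a
        results.append(burden_from_counts(gene, a, n1, c, n2, spec, or_method))
    results.sort(key=lambda r: (r.p_two_sided, r.gene))
    return results


def per_variant_test(callset: CallSet, variant_index: int,
                     spec: ThresholdSpec | None = None,
                     or_method: str = "sample") -> BurdenResult:
    """Single-variant carrier-count FET (same machinery as per gene)."""
    col = callset.genotypes.getcol(variant_index).toarray().ravel()
    carrier = col > 0
    a = int((carrier & callset.is_case).sum())
    c = int((carrier & ~callset.is_case).sum())
    return burden_from_counts(str(callset.variant_ids[variant_index]),
                              a, callset.n_cases, c, callset.n_controls,
                              spec, or_method)
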