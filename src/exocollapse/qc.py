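"""Sample gates, variant-level QC filters, and coverage harmonization.

Three independent layers guard a collapsing analysis against technical
artifact:

* sample gates drop contaminated, under-covered, or related individuals;
* variant filters drop calls whose site- and genotype-level metrics fall
  outside sequencing-quality thresholds;
* coverage harmonization drops sites whose sequencing depth is not
  independent of case/control status, since differential coverage mimics
  differential burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .callset import CallSet

# -- sample-level gates ----------------------------------------------------

#: contamination above this fraction excludes a sample
MAX_CONTAMINATION = 0.08
#: samples must cover strictly more than this fraction of CCDS at 10x
MIN_CCDS10X = 0.87


@dataclass(frozen=True)
class SampleMetrics:
    """Precomputed per-sample QC scalars (from VerifyBamID-style tools)."""

    sample_id: str
    contamination: float
    ccds10x_frac: float

    def __post_init__(self):
        for name in ("contamination", "ccds10x_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


def _max_independent_set(nodes: list, edges: set) -> list:
    """Deterministic maximum independent set (branch and bound).

    Ties between equally large sets break toward the lexicographically
    smallest sorted node tuple, so pruning is reproducible.
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def key(sel):
        return (len(sel), [str(x) for x in sorted(sel, reverse=True)])

    def best(remaining: frozenset) -> tuple:
        if not remaining:
            return ()
        v = max(remaining, key=lambda n: (len(adj[n] & remaining), str(n)))
        without = best(remaining - {v})
        with_v = (v,) + best(remaining - {v} - adj[v])
        # larger set wins; equal size -> smaller sorted tuple wins
        if len(with_v) != len(without):
            return max(with_v, without, key=len)
        return min(with_v, without, key=lambda s: sorted(map(str, s)))

    return sorted(best(frozenset(nodes)))


def _greedy_independent_set(nodes: list, edges: set) -> list:
    """Fallback for implausibly large kinship components (>28 samples)."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    alive = set(nodes)
    while any(adj[n] & alive for n in alive):
        worst = max(alive, key=lambda n: (len(adj[n] & alive), str(n)))
        alive.discard(worst)
    return sorted(alive)


def filter_samples(metrics, kinship_pairs=(),
                   max_contamination: float = MAX_CONTAMINATION,
                   min_ccds10x: float = MIN_CCDS10X,
                   ) -> tuple[set, list[tuple[str, str]]]:
    """Apply sample gates; returns (kept sample ids, exclusion log).

    Kinship pairs (related up to third degree) are pruned by keeping, in
    each relatedness component, a maximum set of mutually unrelated
    samples. The exclusion log is a list of ``(sample_id, reason)``.
    """
    ids = [m.sample_id for m in metrics]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in metrics")
    known = set(ids)
    for a, b in kinship_pairs:
        if a not in known or b not in known:
            raise ValueError(f"kinship pair ({a}, {b}) references unknown sample")

    log: list[tuple[str, str]] = []
    kept = set()
    for m in metrics:
        if m.contamination > max_contamination:
            log.append((m.sample_id,
                        f"contamination {m.contamination:.3g} > "
                        f"{max_contamination:g}"))
        elif m.ccds10x_frac <= min_ccds10x:
            log.append((m.sample_id,
                        f"ccds10x_frac {m.ccds10x_frac:.3g} <= "
                        f"{min_ccds10x:g}"))
        else:
            kept.add(m.sample_id)

    # relatedness pruning on the surviving samples
    edges = {(a, b) for a, b in kinship_pairs if a in kept and b in kept}
    if edges:
        comp_nodes = sorted({n for e in edges for n in e})
        # connected components
        parent = {n: n for n in comp_nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        comps: dict[str, list] = {}
        for n in comp_nodes:
            comps.setdefault(find(n), []).append(n)
        for nodes in comps.values():
            sub = {(a, b) for a, b in edges if a in set(nodes)}
            if len(nodes) <= 28:
                keep_comp = set(_max_independent_set(nodes, sub))
            else:
                keep_comp = set(_greedy_independent_set(nodes, sub))
            for n in sorted(set(nodes) - keep_comp):
                kept.discard(n)
                log.append((n, "related (third degree or closer)"))
    return kept, log


# -- variant-level QC ------------------------------------------------------


@dataclass(frozen=True)
class VariantQCMetrics:
    """Site/genotype metrics feeding the pass/fail conjunction.

    Rank-sum statistics may be absent (``None``) when all reads support a
    single allele; absence is not evidence of bias, so those rules pass.
    ``alt_allele_ratio`` is only meaningful (and only checked) for
    heterozygous calls.
    """

    qual: float
    qd: float
    gq: float
    mq: float
    depth: float
    fs: float
    read_pos_rank_sum: float | None = None
    mq_rank_sum: float | None = None
    alt_allele_ratio: float | None = None
    is_indel: bool = False
    evs_failure: bool = False

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")
        if self.alt_allele_ratio is not None \
                and not 0.0 <= self.alt_allele_ratio <= 1.0:
            raise ValueError(
                f"alt_allele_ratio {self.alt_allele_ratio} outside [0,1]")


@dataclass(frozen=True)
class QCThresholds:
    """The variant-QC rule constants (all bounds inclusive unless noted)."""

    min_qual: float = 30.0
    min_qd: float = 2.0
    min_gq: float = 20.0
    min_read_pos_rank_sum: float = -3.0
    min_mq: float = 40.0
    min_mq_rank_sum_exclusive: float = -10.0   # strict >
    min_depth: float = 10.0
    max_fs_snv: float = 60.0
    max_fs_indel: float = 200.0
    min_het_alt_ratio: float = 0.25


DEFAULT_QC = QCThresholds()


def apply_variant_qc(v: VariantQCMetrics,
                     thresholds: QCThresholds = DEFAULT_QC,
                     ) -> tuple[bool, list[str]]:
    """Evaluate the QC conjunction; returns (passed, failed rule names)."""
    t = thresholds
    failed = []
    if v.qual < t.min_qual:
        failed.append("qual")
    if v.qd < t.min_qd:
        failed.append("qd")
    if v.gq < t.min_gq:
        failed.append("gq")
    if v.read_pos_rank_sum is not None \
            and v.read_pos_rank_sum < t.min_read_pos_rank_sum:
        failed.append("read_pos_rank_sum")
    if v.mq < t.min_mq:
        failed.append("mq")
    if v.mq_rank_sum is not None \
            and not v.mq_rank_sum > t.min_mq_rank_sum_exclusive:
        failed.append("mq_rank_sum")
    if v.depth < t.min_depth:
        failed.append("depth")
    max_fs = t.max_fs_indel if v.is_indel else t.max_fs_snv
    if v.fs > max_fs:
        failed.append("fs")
    if v.alt_allele_ratio is not None \
            and v.alt_allele_ratio < t.min_het_alt_ratio:
        failed.append("alt_allele_ratio")
    if v.evs_failure:
        failed.append("evs_failure")
    return not failed, failed


# -- coverage harmonization ------------------------------------------------


def coverage_independence_test(covered_cases: int, n_cases: int,
                               covered_controls: int, n_controls: int,
                               tested: str = "cases") -> float:
    """Two-sided binomial test of coverage/status independence at one site.

    The null pools the covered fraction across cohorts and asks whether
    the tested cohort's covered count is binomially consistent with it
    (minimum-likelihood two-sided summation, the convention of
    ``scipy.stats.binomtest``).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    if not 0 <= covered_cases <= n_cases:
        raise ValueError("covered_cases outside [0, n_cases]")
    if not 0 <= covered_controls <= n_controls:
        raise ValueError("covered_controls outside [0, n_controls]")
    pooled = (covered_cases + covered_controls) / (n_cases + n_controls)
    if tested == "cases":
        k, n = covered_cases, n_cases
    elif tested == "controls":
        k, n = covered_controls, n_controls
    else:
        raise ValueError(f"tested must be 'cases' or 'controls', got {tested!r}")
    if pooled in (0.0, 1.0):
        return 1.0
    return binomtest(k, n, pooled, alternative="two-sided").pvalue


@dataclass
class HarmonizationResult:
    retained: np.ndarray                  # variant column indices kept
    excluded: list = field(default_factory=list)  # (index, variant_id, p)
    alpha: float = 0.01


def harmonize_sites(callset: CallSet, alpha: float = 0.01,
                    tested: str = "cases") -> HarmonizationResult:
    """Exclude sites whose coverage test reaches p <= alpha."""
    cov_case, cov_ctrl = callset.covered_counts()
    n1, n2 = callset.n_cases, callset.n_controls
    retained, excluded = [], []
    cache: dict[tuple[int, int], float] = {}
    for j in range(callset.n_variants):
        key = (int(cov_case[j]), int(cov_ctrl[j]))
        p = cache.get(key)
        if p is None:
            p = cache[key] = coverage_independence_test(
                key[0], n1, key[1], n2, tested=tested)
        if p <= alpha:
            excluded.append((j, callset.variant_ids[j], p))
        else:
            retained.append(j)
    return HarmonizationResult(np.array(retained, dtype=int), excluded, alpha)
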