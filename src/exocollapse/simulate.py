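"""Synthetic annotated case/control exome cohorts.

The generator emulates the statistical structure a gene-collapsing burden
scan assumes: per-gene panels of rare variants with effect classes,
reference-population allele frequencies, predictor annotations
(PolyPhen-2 HumVar labels, TraP scores) and site QC metrics; genotypes
drawn identically in cases and controls for null genes; and optional
implanted enrichments where per-sample carrier indicators follow
cohort-specific Bernoulli frequencies.

Carrier frequencies in the default configuration are deliberately high
(median rare-LOF carrier fraction per gene around 15%) so the discrete
Fisher exact test's null p-value distribution is dense enough for
median-based inflation diagnostics; see docs/methods.md for why realistic
rare-variant sparsity deflates lambda on a 2,000-gene panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .callset import ALT_HOM, HET, MISSING, CallSet
from .models import EFFECT_CLASSES, LOF_CLASSES, VariantRecord
from .qc import DEFAULT_QC, SampleMetrics, VariantQCMetrics, apply_variant_qc

DEFAULT_EFFECT_WEIGHTS = {
    "stop_gained": 0.16,
    "frameshift": 0.13,
    "splice_acceptor": 0.055,
    "splice_donor": 0.055,
    "missense": 0.35,
    "synonymous": 0.18,
    "splice_region": 0.07,
}

DEFAULT_GNOMAD_POPS = ("afr", "amr", "eas", "fin", "nfe", "sas")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MAFSpectrum:
    """Allele-frequency spectrum of simulated variants.

    Rare variants draw ``af = rare_af_cap * Beta(rare_beta_a, rare_beta_b)``
    (all below the 1% qualifying ceiling); a fraction are ultra-rare
    (uniform below ``ultra_rare_max``, substrate for the MAF <= 0.01%
    models); and each gene receives on average ``common_site_rate`` common
    variants (uniform over ``common_af_range``, substrate for the
    common-LOF complement and ceiling tests).
    """

    rare_beta_a: float = 2.5
    rare_beta_b: float = 1.0
    rare_af_cap: float = 0.0045
    ultra_rare_frac: float = 0.10
    ultra_rare_max: float = 1e-4
    common_site_rate: float = 0.3
    common_af_range: tuple = (0.02, 0.2)
    gnomad_jitter_sigma: float = 0.05


@dataclass(frozen=True)
class Enrichment:
    """One implanted case/control carrier-frequency contrast."""

    gene_id: str
    case_carrier_freq: float
    control_carrier_freq: float
    model_name: str = "lof"
    zygosity: str = "het"        # het | hom | two_het

    def __post_init__(self):
        for f in (self.case_carrier_freq, self.control_carrier_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carrier frequency {f} outside [0,1]")
        if self.zygosity not in ("het", "hom", "two_het"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def odds_ratio(self) -> float:
        f1, f2 = self.case_carrier_freq, self.control_carrier_freq
        return (f1 / (1 - f1)) / (f2 / (1 - f2))


@dataclass
class SimulationConfig:
    n_cases: int = 849
    n_controls: int = 15640
    n_genes: int = 2000
    variants_per_gene: float = 110.0
    effect_class_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS))
    maf_spectrum: MAFSpectrum = field(default_factory=MAFSpectrum)
    enrichments: list = field(default_factory=list)
    coverage_imbalance_sites: int = 0
    case_cover_frac: float = 1.0
    control_cover_frac: float = 1.0
    missing_rate: float = 0.0
    gnomad_pops: tuple = DEFAULT_GNOMAD_POPS
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.variants_per_gene <= 0:
            raise ValueError("variants_per_gene must be positive")
        w = self.effect_class_weights
        unknown = set(w) - EFFECT_CLASSES
        if unknown:
            raise ValueError(f"unknown effect classes {sorted(unknown)}")
        if any(x < 0 for x in w.values()) or \
                not math.isclose(sum(w.values()), 1.0, abs_tol=1e-9):
            raise ValueError("effect class weights must be >= 0 and sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0,1)")
        for f in (self.case_cover_frac, self.control_cover_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"coverage fraction {f} outside [0,1]")
        self.enrichments = [
            e if isinstance(e, Enrichment) else Enrichment(*e)
            for e in self.enrichments
        ]


@dataclass
class SimulatedCohort:
    callset: CallSet
    annotations: pd.DataFrame
    sample_metrics: list

    @property
    def records(self) -> list:
        return records_from_table(self.annotations)


# -- helpers ---------------------------------------------------------------


def _sample_indices(rng, n: int, k: int, offset: int = 0) -> np.ndarray:
    """k distinct uniform indices in [offset, offset+n)."""
    if k <= 0:
        return np.empty(0, dtype=np.int64)
    if k >= n:
        return offset + np.arange(n, dtype=np.int64)
    if k > n // 3:
        return offset + rng.permutation(n)[:k].astype(np.int64)
    picked = np.unique(rng.integers(0, n, size=int(k * 1.2) + 8))
    while picked.size < k:
        picked = np.unique(np.concatenate(
            [picked, rng.integers(0, n, size=int(k * 1.2) + 8)]))
    return offset + rng.permutation(picked)[:k].astype(np.int64)


def _apportion(n: int, weights: dict) -> dict:
    """Largest-remainder apportionment of n variants across classes."""
    names = sorted(weights)
    raw = {c: n * weights[c] for c in names}
    counts = {c: int(raw[c]) for c in names}
    short = n - sum(counts.values())
    by_rem = sorted(names, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def _passing_qc_metrics(rng) -> dict:
    """Site QC metrics drawn from passing-heavy sequencing distributions."""
    return {
        "qual": float(max(0.0, rng.normal(200, 60))),
        "qd": float(max(0.0, rng.normal(15, 5))),
        "gq": float(np.clip(rng.normal(70, 18), 0, 99)),
        "read_pos_rank_sum": float(rng.normal(0, 1.2)),
        "mq": float(np.clip(rng.normal(60, 4), 0, 70)),
        "mq_rank_sum": float(rng.normal(0, 2)),
        "depth": float(10 + rng.poisson(55)),
        "fs": float(rng.exponential(10)),
        "alt_allele_ratio": float(np.clip(rng.normal(0.5, 0.08), 0, 1)),
        "evs_failure": bool(rng.random() < 0.002),
    }


_ENRICH_EFFECT = {
    # model name -> (effect, polyphen, trap) for the implanted variants
    "lof": ("stop_gained", None, None),
    "lof_missense": ("missense", "probably_damaging", None),
    "lof_missense_splicing": ("splice_region", None, 0.55),
    "maf5": ("missense", "probably_damaging", None),
    "maf0.1": ("stop_gained", None, None),
    "maf0.01": ("stop_gained", None, None),
    "recessive": ("missense", "probably_damaging", None),
    "synonymous_control": ("synonymous", None, None),
    "common_lof": ("stop_gained", None, None),
}


def _variant_row(chrom, pos, gene, effect, rng):
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    is_indel = effect == "frameshift"
    if is_indel:
        alt = ref + "A"
    return {"chrom": chrom, "pos": int(pos), "ref": str(ref),
            "alt": str(alt), "gene": gene, "effect": effect,
            "is_indel": is_indel}


# -- main entry ------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate an annotated cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_cases, config.n_controls
    n = n1 + n2
    spec = config.maf_spectrum
    pops = list(config.gnomad_pops)

    sample_ids = np.array(
        [f"case{i + 1:05d}" for i in range(n1)]
        + [f"ctrl{i + 1:05d}" for i in range(n2)], dtype=object)
    is_case = np.zeros(n, dtype=bool)
    is_case[:n1] = True

    genes = [f"GENE{g + 1:05d}" for g in range(config.n_genes)]
    enrich_by_gene: dict[str, list[Enrichment]] = {}
    for e in config.enrichments:
        if e.gene_id not in set(genes):
            raise ValueError(f"enrichment gene {e.gene_id!r} not simulated "
                             f"(use GENE00001..GENE{config.n_genes:05d})")
        enrich_by_gene.setdefault(e.gene_id, []).append(e)

    rows: list[dict] = []          # annotation rows
    gt_rows: list[np.ndarray] = []  # COO pieces
    gt_cols: list[np.ndarray] = []
    gt_data: list[np.ndarray] = []

    def add_genotypes(j: int, idx: np.ndarray, code: int):
        if idx.size:
            gt_rows.append(idx)
            gt_cols.append(np.full(idx.size, j, dtype=np.int64))
            gt_data.append(np.full(idx.size, code, dtype=np.int8))

    def draw_af(ultra_ok=True):
        if ultra_ok and rng.random() < spec.ultra_rare_frac:
            return float(rng.uniform(1e-6, spec.ultra_rare_max))
        return float(spec.rare_af_cap * rng.beta(spec.rare_beta_a,
                                                 spec.rare_beta_b))

    def gnomad_jitter(af):
        out = {}
        for pop in pops:
            out[pop] = float(np.clip(
                af * rng.lognormal(0.0, spec.gnomad_jitter_sigma), 0.0, 0.5))
        return out

    j = 0
    for g, gene in enumerate(genes):
        chrom = str(g % 22 + 1)
        base_pos = 1_000_000 + g * 100_000
        enrichments = enrich_by_gene.get(gene, [])
        nv = max(1, int(rng.poisson(config.variants_per_gene)))
        counts = _apportion(nv, config.effect_class_weights)

        k = 0
        for effect in sorted(counts):
            for _ in range(counts[effect]):
                af = draw_af()
                if enrichments:
                    # background in enriched genes must not qualify under
                    # any damaging model: benign missense only
                    effect_eff, polyphen, trap = "missense", "benign", None
                elif effect == "missense":
                    effect_eff = effect
                    polyphen = str(rng.choice(
                        ["benign", "possibly_damaging", "probably_damaging"],
                        p=[0.5, 0.2, 0.3]))
                    trap = None
                elif effect in ("synonymous", "splice_region"):
                    effect_eff, polyphen = effect, None
                    trap = float(np.clip(rng.beta(0.5, 8.0), 0, 1))
                else:
                    effect_eff, polyphen, trap = effect, None, None
                row = _variant_row(chrom, base_pos + 10 * k, gene,
                                   effect_eff, rng)
                row.update(_passing_qc_metrics(rng))
                row["polyphen_humvar"] = polyphen
                row["trap_score"] = trap
                for pop, v in gnomad_jitter(af).items():
                    row[f"gnomad_af_{pop}"] = v
                rows.append(row)
                # genotypes: iid Bernoulli across the whole cohort
                k_het = rng.binomial(n, 2 * af * (1 - af))
                k_hom = rng.binomial(n, af * af)
                idx = _sample_indices(rng, n, k_het + k_hom)
                add_genotypes(j, idx[:k_hom], ALT_HOM)
                add_genotypes(j, idx[k_hom:], HET)
                j += 1
                k += 1

        # occasional common variant (above the 1% ceiling)
        if rng.random() < spec.common_site_rate and not enrichments:
            af = float(rng.uniform(*spec.common_af_range))
            effect = str(rng.choice(sorted(config.effect_class_weights),
                                    p=[config.effect_class_weights[c]
                                       for c in sorted(
                                           config.effect_class_weights)]))
            row = _variant_row(chrom, base_pos + 10 * k, gene, effect, rng)
            row.update(_passing_qc_metrics(rng))
            row["polyphen_humvar"] = ("probably_damaging"
                                      if effect == "missense" else None)
            row["trap_score"] = None
            for pop, v in gnomad_jitter(af).items():
                row[f"gnomad_af_{pop}"] = v
            rows.append(row)
            k_het = rng.binomial(n, 2 * af * (1 - af))
            k_hom = rng.binomial(n, af * af)
            idx = _sample_indices(rng, n, k_het + k_hom)
            add_genotypes(j, idx[:k_hom], ALT_HOM)
            add_genotypes(j, idx[k_hom:], HET)
            j += 1
            k += 1

        # implanted enrichments: per-sample Bernoulli carrier indicators,
        # one qualifying variant per carrier, spread over enough distinct
        # variants that each stays below the model's MAF ceiling
        for e in enrichments:
            effect, polyphen, trap = _ENRICH_EFFECT[e.model_name]
            common = e.model_name == "common_lof"
            n_case_carriers = rng.binomial(n1, e.case_carrier_freq)
            n_ctrl_carriers = rng.binomial(n2, e.control_carrier_freq)
            case_idx = _sample_indices(rng, n1, n_case_carriers)
            ctrl_idx = _sample_indices(rng, n2, n_ctrl_carriers, offset=n1)
            carriers = np.concatenate([case_idx, ctrl_idx])
            if common:
                n_var = 1
            else:
                lim1 = max(1, int(0.019 * n1))
                lim2 = max(1, int(0.019 * n2))
                n_var = max(1, math.ceil(max(n_case_carriers, 1) / lim1),
                            math.ceil(max(n_ctrl_carriers, 1) / lim2))
            per_variant = 2 if e.zygosity == "two_het" else 1
            af0 = (e.control_carrier_freq / 2) or 1e-4
            if common:
                af0 = max(af0, 0.02)
            else:
                af0 = min(af0 / n_var, 0.0090)
            start = j
            for v in range(n_var * per_variant):
                row = _variant_row(chrom, base_pos + 10 * (k + v), gene,
                                   effect, rng)
                row.update(_passing_qc_metrics(rng))
                row["evs_failure"] = False
                row["qual"], row["qd"], row["gq"] = 500.0, 20.0, 90.0
                row["fs"], row["mq"], row["depth"] = 1.0, 60.0, 80.0
                row["polyphen_humvar"] = polyphen
                row["trap_score"] = trap
                for pop in pops:
                    row[f"gnomad_af_{pop}"] = af0
                rows.append(row)
            code = ALT_HOM if e.zygosity == "hom" else HET
            for i, s in enumerate(carriers):
                v = i % n_var
                if e.zygosity == "two_het":
                    add_genotypes(start + 2 * v, np.array([s]), HET)
                    add_genotypes(start + 2 * v + 1, np.array([s]), HET)
                else:
                    add_genotypes(start + v, np.array([s]), code)
            j += n_var * per_variant
            k += n_var * per_variant

    n_variants = j
    if gt_rows:
        coo = sparse.coo_matrix(
            (np.concatenate(gt_data),
             (np.concatenate(gt_rows), np.concatenate(gt_cols))),
            shape=(n, n_variants), dtype=np.int8)
        genotypes = coo.tocsr()
    else:
        genotypes = sparse.csr_matrix((n, n_variants), dtype=np.int8)

    # optional missingness
    if config.missing_rate > 0:
        n_miss = rng.binomial(n * n_variants, config.missing_rate)
        flat = _sample_indices(rng, n * n_variants, n_miss)
        miss = sparse.coo_matrix(
            (np.full(flat.size, 1, dtype=np.int8),
             (flat // n_variants, flat % n_variants)),
            shape=(n, n_variants), dtype=np.int8).tocsr()
        genotypes = genotypes.tolil()
        for r, cidx in zip(*miss.nonzero()):
            genotypes[r, cidx] = MISSING
        genotypes = genotypes.tocsr()

    ann = pd.DataFrame(rows)
    callset = CallSet(
        sample_ids=sample_ids,
        is_case=is_case,
        variant_ids=[f"{r['chrom']}:{r['pos']}:{r['ref']}:{r['alt']}"
                     for r in rows],
        genotypes=genotypes,
        meta={"seed": config.seed},
    )
    case_af, ctrl_af = callset.cohort_allele_frequencies()
    ann["case_af"] = case_af
    ann["control_af"] = ctrl_af
    ann["qc_pass"] = [
        apply_variant_qc(VariantQCMetrics(
            qual=r["qual"], qd=r["qd"], gq=r["gq"], mq=r["mq"],
            depth=r["depth"], fs=r["fs"],
            read_pos_rank_sum=r["read_pos_rank_sum"],
            mq_rank_sum=r["mq_rank_sum"],
            alt_allele_ratio=r["alt_allele_ratio"],
            is_indel=r["is_indel"], evs_failure=r["evs_failure"]),
            DEFAULT_QC)[0]
        for r in rows]

    metrics = [SampleMetrics(sid,
                             contamination=float(rng.uniform(0, 0.05)),
                             ccds10x_frac=float(rng.uniform(0.90, 0.995)))
               for sid in sample_ids]

    cohort = SimulatedCohort(callset, ann, metrics)
    if config.coverage_imbalance_sites:
        cohort.callset = simulate_coverage_imbalance(
            callset, config.coverage_imbalance_sites,
            config.case_cover_frac, config.control_cover_frac,
            seed=int(rng.integers(2 ** 31)))
    return cohort


def records_from_table(ann: pd.DataFrame) -> list[VariantRecord]:
    """Annotation DataFrame -> VariantRecord list (column order preserved)."""
    pops = [c[len("gnomad_af_"):] for c in ann.columns
            if c.startswith("gnomad_af_")]
    records = []
    for r in ann.itertuples(index=False):
        d = r._asdict()
        polyphen = d.get("polyphen_humvar")
        if polyphen is not None and (not isinstance(polyphen, str)
                                     or polyphen == ""):
            polyphen = None
        trap = d.get("trap_score")
        if trap is not None and (isinstance(trap, float)
                                 and math.isnan(trap)):
            trap = None
        records.append(VariantRecord(
            chrom=str(d["chrom"]), pos=int(d["pos"]), ref=str(d["ref"]),
            alt=str(d["alt"]), gene=str(d["gene"]), effect=str(d["effect"]),
            gnomad_afs={p: float(d[f"gnomad_af_{p}"]) for p in pops},
            case_af=float(d.get("case_af", 0.0)),
            control_af=float(d.get("control_af", 0.0)),
            polyphen_humvar=polyphen,
            trap_score=None if trap is None else float(trap),
            qc_pass=bool(d.get("qc_pass", True)),
        ))
    return records


def make_fixture_from_counts(a: int, n1: int, c: int, n2: int,
                             gene_id: str = "GENE", effect: str = "stop_gained",
                             zygosity: str = "het", n_variants: int | None = None,
                             ) -> SimulatedCohort:
    """Deterministic cohort whose collapsed table is exactly (a, n1-a, c, n2-c).

    Case carriers occupy the first ``a`` case slots, control carriers the
    first ``c`` control slots.  Carriers are spread round-robin over
    enough distinct variants that every variant's cohort allele frequency
    stays below the 1% qualifying ceiling (override with ``n_variants``,
    e.g. ``1`` for single-variant tests). ``zygosity`` controls the
    implanted genotype: ``het``, ``hom`` (alt-homozygous), or ``two_het``
    (a putative compound heterozygote over paired variants).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("cohort sizes must be >= 1")
    if not 0 <= a <= n1:
        raise ValueError(f"case carriers {a} outside [0, {n1}]")
    if not 0 <= c <= n2:
        raise ValueError(f"control carriers {c} outside [0, {n2}]")
    if zygosity not in ("het", "hom", "two_het"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if effect not in EFFECT_CLASSES:
        raise ValueError(f"unknown effect {effect!r}")

    if n_variants is None:
        # keep each variant's realized cohort AF below the 1% ceiling;
        # alt-homozygous carriers contribute two alleles
        alleles = 2 if zygosity == "hom" else 1
        lim1 = max(1, int(0.019 * n1 / alleles))
        lim2 = max(1, int(0.019 * n2 / alleles))
        n_var = max(1, math.ceil(a / lim1) if a else 1,
                    math.ceil(c / lim2) if c else 1)
    else:
        n_var = int(n_variants)
    per_variant = 2 if zygosity == "two_het" else 1
    n_cols = n_var * per_variant

    n = n1 + n2
    sample_ids = np.array([f"case{i + 1:05d}" for i in range(n1)]
                          + [f"ctrl{i + 1:05d}" for i in range(n2)],
                          dtype=object)
    is_case = np.zeros(n, dtype=bool)
    is_case[:n1] = True
    code = ALT_HOM if zygosity == "hom" else HET
    r_idx, c_idx, data = [], [], []
    carriers = list(range(a)) + list(range(n1, n1 + c))
    for i, s in enumerate(carriers):
        v = i % n_var
        if zygosity == "two_het":
            for jj in (2 * v, 2 * v + 1):
                r_idx.append(s)
                c_idx.append(jj)
                data.append(HET)
        else:
            r_idx.append(s)
            c_idx.append(v)
            data.append(code)
    genotypes = sparse.coo_matrix(
        (np.array(data, dtype=np.int8), (r_idx, c_idx)),
        shape=(n, n_cols), dtype=np.int8).tocsr()

    rows = []
    for v in range(n_cols):
        row = _variant_row("1", 1_000_000 + 10 * v, gene_id, effect,
                           np.random.default_rng(v))
        row.update({"qual": 500.0, "qd": 20.0, "gq": 90.0,
                    "read_pos_rank_sum": 0.0, "mq": 60.0, "mq_rank_sum": 0.0,
                    "depth": 80.0, "fs": 1.0, "alt_allele_ratio": 0.5,
                    "evs_failure": False,
                    "polyphen_humvar": ("probably_damaging"
                                        if effect == "missense" else None),
                    "trap_score": 0.55 if effect in ("synonymous",
                                                     "splice_region")
                    else None})
        rows.append(row)
    ann = pd.DataFrame(rows)
    callset = CallSet(sample_ids, is_case,
                      [f"{r['chrom']}:{r['pos']}:{r['ref']}:{r['alt']}"
                       for r in rows],
                      genotypes, meta={"fixture": (a, n1, c, n2)})
    case_af, ctrl_af = callset.cohort_allele_frequencies()
    ann["case_af"] = case_af
    ann["control_af"] = ctrl_af
    ann["qc_pass"] = True
    metrics = [SampleMetrics(sid, contamination=0.0, ccds10x_frac=0.99)
               for sid in sample_ids]
    return SimulatedCohort(callset, ann, metrics)


def simulate_coverage_imbalance(callset: CallSet, n_sites: int,
                                case_cover_frac: float,
                                control_cover_frac: float,
                                seed: int = 0) -> CallSet:
    """Knock out coverage at ``n_sites`` random sites, per-cohort Bernoulli.

    Designated sites get covered indicators drawn at the stated fractions
    (cases at ``case_cover_frac``, controls at ``control_cover_frac``);
    all other sites stay fully covered. Genotypes at uncovered slots
    become missing, preserving the carrier-implies-covered invariant.
    """
    for f in (case_cover_frac, control_cover_frac):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"coverage fraction {f} outside [0,1]")
    if n_sites > callset.n_variants:
        raise ValueError(
            f"n_sites {n_sites} exceeds {callset.n_variants} variants")
    rng = np.random.default_rng(seed)
    sites = np.sort(rng.choice(callset.n_variants, size=n_sites,
                               replace=False))
    n = callset.n_samples
    case_rows = np.flatnonzero(callset.is_case)
    ctrl_rows = np.flatnonzero(~callset.is_case)
    u_rows, u_cols = [], []
    for jj in sites:
        unc_case = case_rows[rng.random(case_rows.size) >= case_cover_frac]
        unc_ctrl = ctrl_rows[rng.random(ctrl_rows.size) >= control_cover_frac]
        unc = np.concatenate([unc_case, unc_ctrl])
        u_rows.append(unc)
        u_cols.append(np.full(unc.size, jj, dtype=np.int64))
    if u_rows:
        rows = np.concatenate(u_rows)
        cols = np.concatenate(u_cols)
    else:
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
    uncovered = sparse.coo_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)),
        shape=callset.genotypes.shape).tocsr()

    genotypes = callset.genotypes.copy().tolil()
    carrier_overlap = callset.genotypes.multiply(uncovered).tocoo()
    for r, cc in zip(carrier_overlap.row, carrier_overlap.col):
        genotypes[r, cc] = MISSING
    out = CallSet(callset.sample_ids, callset.is_case,
                  list(callset.variant_ids), genotypes.tocsr(),
                  uncovered=uncovered, meta=dict(callset.meta))
    out.validate_coverage()
    return out
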