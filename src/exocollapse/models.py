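"""Qualifying-variant models for gene-collapsing burden analysis.

A *qualifying variant* is a variant whose population frequency, predicted
effect, and predictor annotations satisfy one named rule set (a model).
Collapsing then reduces a gene to the binary per-sample indicator "carries
at least one qualifying variant", whose frequency is compared between
cases and controls.

The built-in registry reproduces a nine-model design used in case/control
exome studies: a primary rare loss-of-function (LOF) model, nested
extensions adding PolyPhen-2 damaging missense and TraP-predicted splicing
disruptions, three alternative minor-allele-frequency ceilings, a
recessive model, a rare-synonymous negative control, and a complementary
common-LOF screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .callset import CallSet

EFFECT_CLASSES = frozenset({
    "stop_gained", "frameshift", "splice_acceptor", "splice_donor",
    "start_lost", "stop_lost", "missense", "synonymous", "splice_region",
})

#: protein-truncating / canonical-splice-disrupting classes
LOF_CLASSES = frozenset({
    "stop_gained", "frameshift", "splice_acceptor", "splice_donor",
    "start_lost", "stop_lost",
})

POLYPHEN_LABELS = frozenset(
    {"benign", "possibly_damaging", "probably_damaging"})
POLYPHEN_DAMAGING = frozenset({"possibly_damaging", "probably_damaging"})

#: classes a TraP splicing-rescue clause can qualify (canonical splice
#: donors/acceptors already count as LOF)
TRAP_RESCUE_CLASSES = frozenset({"synonymous", "splice_region"})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele with the fields qualification needs."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    gnomad_afs: dict = field(default_factory=dict)
    case_af: float = 0.0
    control_af: float = 0.0
    polyphen_humvar: str | None = None
    trap_score: float | None = None
    qc_pass: bool = True

    def __post_init__(self):
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        for name, af in self.all_afs():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {name}={af} outside [0,1]")
        if self.polyphen_humvar is not None \
                and self.polyphen_humvar not in POLYPHEN_LABELS:
            raise ValueError(
                f"unknown PolyPhen-2 HumVar label {self.polyphen_humvar!r}")
        if self.trap_score is not None and not 0.0 <= self.trap_score <= 1.0:
            raise ValueError(f"TraP score {self.trap_score} outside [0,1]")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def all_afs(self):
        yield "case_af", self.case_af
        yield "control_af", self.control_af
        for pop, af in self.gnomad_afs.items():
            yield f"gnomad_{pop}", af

    def max_maf(self) -> float:
        """Largest minor-allele frequency across cohorts and populations."""
        return max(min(af, 1.0 - af) for _, af in self.all_afs())


@dataclass(frozen=True)
class QualifyingModel:
    """A named rule set selecting qualifying variants.

    Exactly one of ``maf_max`` (rare models: the folded MAF must be at or
    below the ceiling in *every* reference population and both sequencing
    cohorts) or ``maf_min`` (the complementary common screen: the folded
    MAF must exceed the floor in at least one population/cohort) is set;
    the two conventions make a rare model and its common complement
    partition the frequency-unconstrained set.
    """

    name: str
    effect_classes: frozenset
    maf_max: float | None = None
    maf_min: float | None = None
    require_polyphen_damaging: bool = False
    trap_min: float | None = None
    zygosity: str = "dominant"
    in_study_correction: bool = True

    def __post_init__(self):
        if (self.maf_max is None) == (self.maf_min is None):
            raise ValueError("exactly one of maf_max/maf_min must be set")
        if self.zygosity not in ("dominant", "recessive"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.trap_min is not None and not 0.0 <= self.trap_min <= 1.0:
            raise ValueError("trap_min outside [0,1]")
        unknown = self.effect_classes - EFFECT_CLASSES
        if unknown:
            raise ValueError(f"unknown effect classes {sorted(unknown)}")

    # -- YAML round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "effect_classes": sorted(self.effect_classes),
            "maf_max": self.maf_max,
            "maf_min": self.maf_min,
            "require_polyphen_damaging": self.require_polyphen_damaging,
            "trap_min": self.trap_min,
            "zygosity": self.zygosity,
            "in_study_correction": self.in_study_correction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QualifyingModel":
        d = dict(d)
        d["effect_classes"] = frozenset(d["effect_classes"])
        return cls(**d)


def models_to_yaml(models, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([m.to_dict() for m in models], fh, sort_keys=False)


def models_from_yaml(path) -> list[QualifyingModel]:
    with open(path) as fh:
        return [QualifyingModel.from_dict(d) for d in yaml.safe_load(fh)]


_DAMAGING = LOF_CLASSES | {"missense"} | TRAP_RESCUE_CLASSES


def builtin_registry() -> list[QualifyingModel]:
    """The nine built-in models.

    Seven non-synonymous models count toward the study-wide Bonferroni
    correction; the synonymous negative control and the common-LOF
    complement do not.
    """
    return [
        QualifyingModel("lof", LOF_CLASSES, maf_max=0.01),
        QualifyingModel("lof_missense", LOF_CLASSES | {"missense"},
                        maf_max=0.01, require_polyphen_damaging=True),
        QualifyingModel("lof_missense_splicing", _DAMAGING, maf_max=0.01,
                        require_polyphen_damaging=True, trap_min=0.2),
        QualifyingModel("maf5", _DAMAGING, maf_max=0.05,
                        require_polyphen_damaging=True, trap_min=0.2),
        QualifyingModel("maf0.1", _DAMAGING, maf_max=0.001,
                        require_polyphen_damaging=True, trap_min=0.2),
        QualifyingModel("maf0.01", _DAMAGING, maf_max=0.0001,
                        require_polyphen_damaging=True, trap_min=0.2),
        QualifyingModel("recessive", _DAMAGING, maf_max=0.01,
                        require_polyphen_damaging=True, trap_min=0.2,
                        zygosity="recessive"),
        QualifyingModel("synonymous_control", frozenset({"synonymous"}),
                        maf_max=0.0001, in_study_correction=False),
        QualifyingModel("common_lof", LOF_CLASSES, maf_min=0.01,
                        in_study_correction=False),
    ]


def get_model(name: str) -> QualifyingModel:
    for m in builtin_registry():
        if m.name == name:
            return m
    raise KeyError(f"no built-in model named {name!r}")


def is_qualifying(v: VariantRecord, m: QualifyingModel) -> tuple[bool, str]:
    """Decide whether ``v`` is a qualifying variant under model ``m``.

    Returns ``(qualifies, reason)`` where the reason names the first
    failing criterion (``"qualifies"`` on success).  A variant missing an
    annotation a rule needs (PolyPhen for a required-damaging missense,
    TraP for a splicing rescue) is conservatively non-qualifying with
    reason ``"unannotated"``.
    """
    if not v.qc_pass:
        return False, "qc_fail"
    maf = v.max_maf()
    if m.maf_max is not None and maf > m.maf_max:
        return False, f"maf {maf:.4g} above ceiling {m.maf_max:g}"
    if m.maf_min is not None and maf <= m.maf_min:
        return False, f"maf {maf:.4g} at or below floor {m.maf_min:g}"
    if v.effect not in m.effect_classes:
        return False, f"effect {v.effect} not in model"
    if v.effect in LOF_CLASSES:
        return True, "qualifies"
    if v.effect == "missense":
        if not m.require_polyphen_damaging:
            return True, "qualifies"
        if v.polyphen_humvar is None:
            return False, "unannotated"
        if v.polyphen_humvar in POLYPHEN_DAMAGING:
            return True, "qualifies"
        return False, f"polyphen {v.polyphen_humvar}"
    if v.effect in TRAP_RESCUE_CLASSES and m.trap_min is not None:
        if v.trap_score is None:
            return False, "unannotated"
        if v.trap_score >= m.trap_min:
            return True, "qualifies"
        return False, f"trap {v.trap_score:.3g} below {m.trap_min:g}"
    # synonymous/splice_region admitted without a TraP clause (control model)
    return True, "qualifies"


class GeneCalls:
    """Qualifying genotype calls of one gene, stored as parallel arrays.

    Semantically a set of ``(sample_index, variant_index)`` pairs (with
    the genotype code alongside); iteration yields those pairs, so the
    object can be treated as the call set directly.  Arrays keep the
    footprint small on exome-scale cohorts.
    """

    __slots__ = ("samples", "variants", "genotypes")

    def __init__(self, samples, variants, genotypes):
        self.samples = np.asarray(samples, dtype=np.int64)
        self.variants = np.asarray(variants, dtype=np.int64)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)

    def __len__(self) -> int:
        return self.samples.size

    def __iter__(self):
        return (tuple(p) for p in
                zip(self.samples.tolist(), self.variants.tolist()))

    def __contains__(self, pair) -> bool:
        s, v = pair
        return bool(((self.samples == s) & (self.variants == v)).any())

    def __eq__(self, other) -> bool:
        return set(self) == set(other)

    def __repr__(self) -> str:
        return f"GeneCalls({len(self)} calls)"


def qualifying_sets(callset: CallSet, annotations, m: QualifyingModel,
                    ) -> dict[str, GeneCalls]:
    """Map gene -> qualifying (sample_index, variant_index) calls.

    Only het/alt-hom genotypes at qualifying variants contribute.  The
    callset is expected to be QC-passed and coverage-harmonized;
    ``annotations`` is a sequence of :class:`VariantRecord` aligned with
    the callset's variant columns.
    """
    if len(annotations) != callset.n_variants:
        raise ValueError("annotations not aligned with callset variants")
    qual_idx = []
    for j, rec in enumerate(annotations):
        ok, _ = is_qualifying(rec, m)
        if ok:
            if not rec.gene:
                raise ValueError(
                    f"qualifying variant {rec.variant_id} has no gene symbol")
            qual_idx.append(j)
    out: dict[str, GeneCalls] = {}
    if not qual_idx:
        return out
    qual_idx = np.asarray(qual_idx, dtype=np.int64)
    sub = callset.genotypes.tocsc()[:, qual_idx].tocoo()
    carrier = (sub.data == 1) | (sub.data == 2)
    rows = sub.row[carrier]
    cols = qual_idx[sub.col[carrier]]       # back to original variant index
    gts = sub.data[carrier]
    genes = np.array([annotations[j].gene for j in qual_idx], dtype=object)
    gene_of_call = genes[np.searchsorted(qual_idx, cols)]
    order = np.argsort(gene_of_call, kind="stable")
    rows, cols, gts = rows[order], cols[order], gts[order]
    uniq, starts = np.unique(gene_of_call[order], return_index=True)
    bounds = np.append(starts, rows.size)
    for k, gene in enumerate(uniq):
        sl = slice(bounds[k], bounds[k + 1])
        out[str(gene)] = GeneCalls(rows[sl], cols[sl], gts[sl])
    return out
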