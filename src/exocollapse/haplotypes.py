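"""Hotspot-versus-founder evidence from pre-phased haplotypes.

A recurrent (hotspot) mutation is carried on many distinct haplotype
backgrounds, whereas a founder allele rides a single ancestral haplotype.
Given externally phased genotypes, :func:`count_carrier_haplotypes`
groups the haplotypes carrying a focal alternate allele by exact identity
over their flanking sites, treating haplotypes whose missing data leave
the assignment ambiguous as inconclusive rather than as new groups.

:func:`is_cpg_transition` classifies the classic hotspot mechanism:
spontaneous deamination of 5-methylcytosine at CpG dinucleotides, seen as
C>T on the strand carrying the cytosine (or G>A on the reference strand
when the deaminated cytosine lies on the reverse strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

REF_ALLELE = 0
ALT_ALLELE = 1
MISSING_ALLELE = -1


@dataclass
class PhasedMatrix:
    """Phased haplotypes: two allele vectors per sample.

    ``haplotypes`` has shape ``(n_samples, 2, n_variants)`` with codes
    0=ref, 1=alt, -1=missing.
    """

    sample_ids: list
    variant_ids: list            # (chrom, pos, ref, alt) tuples or strings
    haplotypes: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_samples, 2, n_variants)")
        if self.haplotypes.shape[0] != len(self.sample_ids):
            raise ValueError("sample count mismatch")
        if self.haplotypes.shape[2] != len(self.variant_ids):
            raise ValueError("variant count mismatch")
        bad = set(np.unique(self.haplotypes)) - {0, 1, -1}
        if bad:
            raise ValueError(f"invalid allele codes {sorted(bad)}")

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[2]


def filter_phasing_input(genotypes: np.ndarray, multiallelic,
                         max_missing_rate: float = 0.20,
                         ) -> tuple[np.ndarray, dict]:
    """Select variants usable for haplotype construction.

    ``genotypes`` is ``(n_samples, n_variants)`` with -1 marking missing
    data. Multiallelic sites and sites missing in more than
    ``max_missing_rate`` of samples are removed. Returns the retained
    column indices and a per-rule removal report.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[1] == 0:
        raise ValueError("empty region: no variants to filter")
    multiallelic = np.asarray(multiallelic, dtype=bool)
    if multiallelic.shape != (genotypes.shape[1],):
        raise ValueError("multiallelic flags not aligned with variants")
    missing_rate = (genotypes == MISSING_ALLELE).mean(axis=0)
    drop_missing = missing_rate > max_missing_rate
    keep = ~multiallelic & ~drop_missing
    report = {
        "n_input": int(genotypes.shape[1]),
        "removed_multiallelic": int(multiallelic.sum()),
        "removed_missing": int((drop_missing & ~multiallelic).sum()),
        "n_retained": int(keep.sum()),
    }
    return np.flatnonzero(keep), report


@dataclass
class HaplotypeGroups:
    """Result of grouping focal-allele carrier haplotypes."""

    n_groups: int
    assignments: list = field(default_factory=list)  # (sample_id, hap, group)
    inconclusive: list = field(default_factory=list)  # (sample_id, hap)

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)


def _informative_sites(m: PhasedMatrix, exclude: int) -> np.ndarray:
    """Sites carrying the alternate allele in at least one haplotype."""
    has_alt = (m.haplotypes == ALT_ALLELE).any(axis=(0, 1))
    has_alt[exclude] = False
    return np.flatnonzero(has_alt)


def count_carrier_haplotypes(m: PhasedMatrix, focal,
                             informative_only: bool = True,
                             ) -> HaplotypeGroups:
    """Count distinct haplotype backgrounds carrying the focal alt allele.

    Carrier haplotypes are grouped by exact identity over their flanking
    sites (by default restricted to informative sites, i.e. sites with
    the alternate allele in at least one haplotype). Fully observed
    haplotypes seed the groups; a haplotype with missing flanks joins the
    unique group it is compatible with, is inconclusive when compatible
    with two or more, and founds a new group when compatible with none.
    """
    if focal in m.variant_ids:
        focal_idx = m.variant_ids.index(focal)
    elif isinstance(focal, (int, np.integer)) and 0 <= focal < m.n_variants:
        focal_idx = int(focal)
    else:
        raise ValueError(f"focal variant {focal!r} not in matrix")

    if informative_only:
        flank = _informative_sites(m, focal_idx)
    else:
        flank = np.array([s for s in range(m.n_variants) if s != focal_idx])

    carriers = []                       # (sample_id, hap_index, flank_vector)
    for i, sid in enumerate(m.sample_ids):
        for h in (0, 1):
            if m.haplotypes[i, h, focal_idx] == ALT_ALLELE:
                carriers.append((sid, h, m.haplotypes[i, h, flank]))
    if not carriers:
        warnings.warn("focal alternate allele carried by no haplotype")
        return HaplotypeGroups(0)

    complete = [c for c in carriers if not (c[2] == MISSING_ALLELE).any()]
    partial = [c for c in carriers if (c[2] == MISSING_ALLELE).any()]

    groups: list[np.ndarray] = []       # representative flank patterns
    assignments, inconclusive = [], []
    for sid, h, vec in complete:
        for gi, rep in enumerate(groups):
            if np.array_equal(rep, vec):
                assignments.append((sid, h, gi))
                break
        else:
            groups.append(vec)
            assignments.append((sid, h, len(groups) - 1))

    def compatible(rep, vec):
        known = (rep != MISSING_ALLELE) & (vec != MISSING_ALLELE)
        return bool((rep[known] == vec[known]).all())

    for sid, h, vec in partial:
        hits = [gi for gi, rep in enumerate(groups) if compatible(rep, vec)]
        if len(hits) == 1:
            assignments.append((sid, h, hits[0]))
        elif len(hits) >= 2:
            inconclusive.append((sid, h))
        else:
            groups.append(vec)
            assignments.append((sid, h, len(groups) - 1))

    used = sorted({g for _, _, g in assignments})
    remap = {g: i for i, g in enumerate(used)}
    assignments = [(sid, h, remap[g]) for sid, h, g in assignments]
    return HaplotypeGroups(len(used), assignments, inconclusive)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def is_cpg_transition(context: str, ref: str, alt: str,
                      ) -> tuple[bool, str | None]:
    """Classify a substitution as a CpG-deamination transition.

    ``context`` is the three reference-strand bases centred on the
    variant. Returns ``(True, "+")`` for C>T with a 3' G (the forward
    strand's methylcytosine deaminated), ``(True, "-")`` for G>A with a
    5' C (reverse-strand deamination), else ``(False, None)``.
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise ValueError(f"context must be 3 bases of ACGT, got {context!r}")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError("ref/alt must be single ACGT bases")
    if context[1] != ref:
        raise ValueError(f"context centre {context[1]!r} != ref {ref!r}")
    if ref == "C" and alt == "T" and context[2] == "G":
        return True, "+"
    if ref == "G" and alt == "A" and context[0] == "C":
        return True, "-"
    return False, None
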