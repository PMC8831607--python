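"""Sample-by-variant genotype container for case/control cohorts.

Genotypes are stored sparsely (reference-homozygous is the implicit zero)
because rare-variant cohorts are overwhelmingly ref-hom: a 16k-sample,
80k-variant exome slice holds only a few million non-reference calls.
Coverage is likewise stored as a sparse *uncovered* exception matrix; a
``None`` mask means every genotype was sequenced to adequate depth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

#: genotype codes
REF_HOM = 0
HET = 1
ALT_HOM = 2
MISSING = -1

GT_CODES = frozenset({REF_HOM, HET, ALT_HOM, MISSING})


@dataclass
class CallSet:
    """Genotype + coverage matrix with case/control labels.

    Parameters
    ----------
    sample_ids:
        Ordered sample identifiers (unique).
    is_case:
        Boolean case indicator aligned with ``sample_ids``.
    variant_ids:
        Ordered variant identifiers, conventionally ``chrom:pos:ref:alt``,
        aligned with the columns of ``genotypes``.
    genotypes:
        ``(n_samples, n_variants)`` CSR int8 matrix with codes
        0=ref-hom, 1=het, 2=alt-hom, -1=missing.
    uncovered:
        Optional ``(n_samples, n_variants)`` sparse boolean matrix marking
        genotypes whose site did **not** reach adequate depth (the <10x
        proxy). ``None`` means fully covered.
    """

    sample_ids: np.ndarray
    is_case: np.ndarray
    variant_ids: list
    genotypes: sparse.csr_matrix
    uncovered: sparse.csr_matrix | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.variant_ids = list(self.variant_ids)
        if not sparse.issparse(self.genotypes):
            self.genotypes = sparse.csr_matrix(
                np.asarray(self.genotypes, dtype=np.int8))
        self.genotypes = self.genotypes.tocsr().astype(np.int8)
        n_s, n_v = self.genotypes.shape
        if len(self.sample_ids) != n_s:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_s} genotype rows")
        if len(self.is_case) != n_s:
            raise ValueError("is_case length does not match sample count")
        if len(self.variant_ids) != n_v:
            raise ValueError(
                f"{len(self.variant_ids)} variant ids for {n_v} columns")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if self.genotypes.nnz:
            bad = set(np.unique(self.genotypes.data)) - GT_CODES
            if bad:
                raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if self.uncovered is not None:
            self.uncovered = self.uncovered.tocsr().astype(bool)
            if self.uncovered.shape != self.genotypes.shape:
                raise ValueError("uncovered mask shape mismatch")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    # -- coverage ---------------------------------------------------------
    def covered_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant counts of covered cases and covered controls."""
        n_case, n_ctrl = self.n_cases, self.n_controls
        if self.uncovered is None or self.uncovered.nnz == 0:
            return (np.full(self.n_variants, n_case),
                    np.full(self.n_variants, n_ctrl))
        unc = self.uncovered
        unc_case = np.asarray(
            unc[self.is_case].sum(axis=0)).ravel().astype(int)
        unc_ctrl = np.asarray(
            unc[~self.is_case].sum(axis=0)).ravel().astype(int)
        return n_case - unc_case, n_ctrl - unc_ctrl

    def validate_coverage(self) -> None:
        """Check the invariant: a het/alt-hom call implies a covered site."""
        if self.uncovered is None or self.uncovered.nnz == 0:
            return
        carriers = self.genotypes.copy()
        carriers.data = (carriers.data > 0).astype(np.int8)
        overlap = carriers.multiply(self.uncovered)
        if overlap.nnz:
            r, c = overlap.nonzero()
            raise ValueError(
                f"non-reference genotype at uncovered site, e.g. sample "
                f"{self.sample_ids[r[0]]!r} variant {self.variant_ids[c[0]]!r}")

    # -- slicing ----------------------------------------------------------
    def subset_variants(self, index) -> "CallSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CallSet(
            sample_ids=self.sample_ids,
            is_case=self.is_case,
            variant_ids=[self.variant_ids[i] for i in index],
            genotypes=self.genotypes[:, index],
            uncovered=None if self.uncovered is None
            else self.uncovered[:, index],
            meta=dict(self.meta),
        )

    def subset_samples(self, keep_ids) -> "CallSet":
        keep = set(keep_ids)
        idx = np.array([i for i, s in enumerate(self.sample_ids) if s in keep])
        if len(idx) == 0:
            raise ValueError("no samples retained")
        return CallSet(
            sample_ids=self.sample_ids[idx],
            is_case=self.is_case[idx],
            variant_ids=self.variant_ids,
            genotypes=self.genotypes[idx],
            uncovered=None if self.uncovered is None else self.uncovered[idx],
            meta=dict(self.meta),
        )

    # -- allele frequencies ----------------------------------------------
    def cohort_allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (case_af, control_af) from non-missing genotypes."""
        g = self.genotypes
        alt = g.copy()
        alt.data = np.where(alt.data > 0, alt.data, 0).astype(np.int8)
        miss = g.copy()
        miss.data = (miss.data == MISSING).astype(np.int8)

        def _af(mask):
            n = int(mask.sum())
            alleles = np.asarray(alt[mask].sum(axis=0)).ravel()
            missing = np.asarray(miss[mask].sum(axis=0)).ravel()
            denom = 2.0 * (n - missing)
            with np.errstate(invalid="ignore", divide="ignore"):
                af = np.where(denom > 0, alleles / denom, 0.0)
            return af

        return _af(self.is_case), _af(~self.is_case)

    # -- reproducibility --------------------------------------------------
    def content_hash(self) -> str:
        """SHA-256 over the full content; equal hash <=> identical callset."""
        h = hashlib.sha256()
        h.update("\x00".join(map(str, self.sample_ids)).encode())
        h.update(self.is_case.tobytes())
        h.update("\x00".join(map(str, self.variant_ids)).encode())
        g = self.genotypes.tocsr()
        g.sum_duplicates()
        g.sort_indices()
        for arr in (g.indptr, g.indices, g.data):
            h.update(np.ascontiguousarray(arr).tobytes())
        if self.uncovered is not None:
            u = self.uncovered.tocsr()
            u.sum_duplicates()
            u.sort_indices()
            for arr in (u.indptr, u.indices, u.data):
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()
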