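"""File-format plumbing: VCF (via pysam), annotation/metrics TSVs.

The genotype substrate travels as multi-sample VCF v4.2 with a GT FORMAT
field; annotations, sample metrics, kinship pairs, exclusion logs and
burden results travel as TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
from scipy import sparse

from .callset import ALT_HOM, HET, MISSING, CallSet
from .haplotypes import PhasedMatrix
from .qc import SampleMetrics

_GT_TO_TUPLE = {
    0: (0, 0),
    HET: (0, 1),
    ALT_HOM: (1, 1),
    MISSING: (None, None),
}


def write_vcf(callset: CallSet, path, phased: bool = False) -> None:
    """Write the callset as a multi-sample VCF v4.2 (GT only, 1-based)."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    chroms = []
    for vid in callset.variant_ids:
        chrom = str(vid).split(":")[0]
        if chrom not in chroms:
            chroms.append(chrom)
    for chrom in chroms:
        header.contigs.add(chrom)
    for sid in callset.sample_ids:
        header.add_sample(str(sid))
    dense = callset.genotypes.toarray()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, vid in enumerate(callset.variant_ids):
            chrom, pos, ref, alt = str(vid).split(":")
            rec = out.new_record(contig=chrom, start=int(pos) - 1,
                                 alleles=(ref, alt))
            for i, sid in enumerate(callset.sample_ids):
                rec.samples[str(sid)]["GT"] = _GT_TO_TUPLE[int(dense[i, j])]
                rec.samples[str(sid)].phased = phased
            out.write(rec)


def read_vcf(path, case_ids) -> CallSet:
    """Read a multi-sample VCF into a CallSet; ``case_ids`` labels cases."""
    case_ids = set(case_ids)
    rows, cols, data = [], [], []
    variant_ids = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for j, rec in enumerate(vf):
            alt = rec.alts[0] if rec.alts else "."
            variant_ids.append(f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}")
            for i, sid in enumerate(samples):
                gt = rec.samples[sid].get("GT")
                if gt is None or any(x is None for x in gt):
                    code = MISSING
                else:
                    code = int(sum(gt))
                if code != 0:
                    rows.append(i)
                    cols.append(j)
                    data.append(code)
    genotypes = sparse.coo_matrix(
        (np.array(data, dtype=np.int8), (rows, cols)),
        shape=(len(samples), len(variant_ids)), dtype=np.int8).tocsr()
    return CallSet(
        sample_ids=np.array(samples, dtype=object),
        is_case=np.array([s in case_ids for s in samples]),
        variant_ids=variant_ids,
        genotypes=genotypes,
    )


def read_phased_matrix(path) -> PhasedMatrix:
    """Read a phased VCF (``a|b`` genotypes) into a PhasedMatrix."""
    haps = []
    variant_ids = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            variant_ids.append((rec.chrom, rec.pos, rec.ref, alt))
            col = np.full((len(samples), 2), -1, dtype=np.int8)
            for i, sid in enumerate(samples):
                gt = rec.samples[sid].get("GT")
                if gt is not None and len(gt) == 2:
                    for h in (0, 1):
                        if gt[h] is not None:
                            col[i, h] = min(int(gt[h]), 1)
            haps.append(col)
    haplotypes = np.stack(haps, axis=2) if haps else \
        np.empty((len(samples), 2, 0), dtype=np.int8)
    return PhasedMatrix(samples, variant_ids, haplotypes)


# -- TSVs ------------------------------------------------------------------


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_metrics(metrics, path, is_case=None) -> None:
    df = pd.DataFrame([{
        "sample_id": m.sample_id,
        "contamination": m.contamination,
        "ccds10x_frac": m.ccds10x_frac,
    } for m in metrics])
    if is_case is not None:
        df["status"] = np.where(np.asarray(is_case, dtype=bool),
                                "case", "control")
    df.to_csv(path, sep="\t", index=False)


def read_sample_metrics(path) -> tuple[list, dict]:
    """Returns (SampleMetrics list, sample_id -> status map if present)."""
    df = pd.read_csv(path, sep="\t")
    metrics = [SampleMetrics(str(r.sample_id), float(r.contamination),
                             float(r.ccds10x_frac))
               for r in df.itertuples(index=False)]
    status = {}
    if "status" in df.columns:
        status = dict(zip(df["sample_id"].astype(str), df["status"]))
    return metrics, status


def read_kinship_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_exclusion_log(log, path) -> None:
    pd.DataFrame(log, columns=["sample_id", "reason"]).to_csv(
        path, sep="\t", index=False)


def burden_results_to_frame(results) -> pd.DataFrame:
    """Burden results as a Table-1-style frame (one row per gene)."""
    return pd.DataFrame([{
        "gene": r.gene,
        "case_carriers": r.case_carriers,
        "cases_total": r.cases_total,
        "control_carriers": r.control_carriers,
        "controls_total": r.controls_total,
        "case_freq": r.case_freq,
        "control_freq": r.control_freq,
        "p_value": r.p_two_sided,
        "odds_ratio": np.nan if r.odds_ratio is None else r.odds_ratio,
        "genome_wide": r.genome_wide_flag,
        "study_wide": r.study_wide_flag,
    } for r in results])


def write_burden_results(results, path) -> None:
    burden_results_to_frame(results).to_csv(path, sep="\t", index=False)
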