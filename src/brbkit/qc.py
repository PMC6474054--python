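"""Library-quality metrics for protocol comparison.

Covers the per-sample alignment-category breakdown, mitochondrial rRNA
contamination (by convention measured on MT-RNR1/MT-RNR2 only, the dominant
carriers of mitochondrial signal), gene-detection counts at read
thresholds, the UMI-based duplication estimate, gene-body coverage profiles
in spliced coordinates, and log-scale sample correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._utils import atomic_write
from .quant import CATEGORIES, BarcodeSet, CountMatrices, GeneModel, classify_alignments

DEFAULT_MT_GENES = ("MT-RNR1", "MT-RNR2")


def alignment_breakdown(
    aln_path,
    gm: GeneModel,
    bs: BarcodeSet,
    rs=None,
    r1_path=None,
    strand_mode: str = "forward",
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Per-sample fractions of the five alignment categories.

    Categories follow union-mode read assignment: mapped-to-gene
    (``feature``), ``no_feature``, ``ambiguous``, ``multimapped``,
    ``unmapped``. Rows sum to 1 for samples with at least one read.
    """
    counts = pd.DataFrame(
        0, index=list(bs.sample_ids), columns=list(CATEGORIES), dtype=np.int64
    )
    for sid, _umi, outcome, _rec in classify_alignments(
        aln_path, gm, bs, rs=rs, r1_path=r1_path,
        strand_mode=strand_mode, max_mismatch=max_mismatch,
    ):
        counts.loc[sid, outcome.category] += 1
    return category_fractions(counts)


def category_fractions(cat_counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize category counts; all-zero rows stay zero."""
    totals = cat_counts.sum(axis=1)
    frac = cat_counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return frac


def mt_fraction(
    cm: CountMatrices,
    gm: Optional[GeneModel] = None,
    mt_gene_names: Sequence[str] = DEFAULT_MT_GENES,
    which: str = "reads",
) -> pd.Series:
    """Fraction of counts on the named mitochondrial rRNA genes, per sample.

    Genes are matched by ``gene_name`` when a gene model is supplied
    (falling back to gene id), else by gene id. Returns 0 for samples with
    no counts at all.
    """
    wanted = set(mt_gene_names)
    if gm is not None:
        ids = {
            gid
            for gid in cm.gene_ids
            if gid in gm.genes
            and ((gm.genes[gid].gene_name or gid) in wanted or gid in wanted)
        }
    else:
        ids = {gid for gid in cm.gene_ids if gid in wanted}
    mat = cm.matrix(which)
    mask = np.array([gid in ids for gid in cm.gene_ids])
    total = mat.sum(axis=0).astype(float)
    mt = mat[mask].sum(axis=0).astype(float) if mask.any() else np.zeros(len(cm.sample_ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mt / np.where(total > 0, total, 1), 0.0)
    return pd.Series(frac, index=cm.sample_ids, name="mt_rrna_fraction")


def detected_genes(
    cm: CountMatrices,
    thresholds: Sequence[int] = (0, 1, 5, 10),
    which: str = "reads",
) -> pd.DataFrame:
    """Genes with count strictly above each threshold, per sample.

    ``threshold 0`` is the usual "at least one read" detection rule.
    Counts are non-increasing in the threshold.
    """
    mat = cm.matrix(which)
    data = {t: (mat > t).sum(axis=0) for t in thresholds}
    return pd.DataFrame(data, index=cm.sample_ids)


def umi_duplication(cm: CountMatrices) -> pd.Series:
    """UMI-based duplication rate per sample: 1 - total UMIs / total reads."""
    r = cm.reads.sum(axis=0).astype(float)
    u = cm.umis.sum(axis=0).astype(float)
    frac = np.where(r > 0, 1.0 - u / np.where(r > 0, r, 1), 0.0)
    return pd.Series(frac, index=cm.sample_ids, name="umi_duplication")


def gene_body_coverage(
    aln_path,
    gm: GeneModel,
    bs: BarcodeSet,
    rs=None,
    r1_path=None,
    strand_mode: str = "forward",
    max_mismatch: int = 0,
    bins: int = 100,
    min_gene_len: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Aggregate read coverage along the normalized 5'→3' gene body.

    Every aligned base of every feature-assigned primary read is projected
    onto the spliced (merged-exon) coordinates of its gene, oriented 5'→3'
    (reversed for minus-strand genes), scaled to [0, 1) and accumulated
    into ``bins`` bins, summing over genes at least ``min_gene_len`` long.

    Returns ``(normalized, raw)``: the profile scaled so its maximum bin is
    1 (all zeros when empty), and the raw per-bin aligned-base counts whose
    total equals the number of exonic aligned bases used.
    """
    raw = np.zeros(bins, dtype=np.int64)
    for _sid, _umi, outcome, rec in classify_alignments(
        aln_path, gm, bs, rs=rs, r1_path=r1_path,
        strand_mode=strand_mode, max_mismatch=max_mismatch,
    ):
        if outcome.category != "feature":
            continue
        gene = gm.genes[outcome.gene_id]
        L = gene.spliced_length
        if L < min_gene_len:
            continue
        for gs, ge in rec.get_blocks():
            for sp_a, sp_b in gene.genomic_to_spliced_intervals(gs, ge):
                # distribute each exonic base into its bin
                pos = np.arange(sp_a, sp_b, dtype=np.int64)
                raw += np.bincount(pos * bins // L, minlength=bins)
    peak = raw.max()
    norm = raw / peak if peak > 0 else np.zeros(bins, dtype=float)
    return norm, raw


def correlate_log_counts(
    cm_a: CountMatrices,
    cm_b: CountMatrices,
    pseudocount: float = 1.0,
    which: str = "reads",
) -> pd.DataFrame:
    """Pearson correlation of log2(count + pseudocount) across sample pairs.

    Computed over the intersection of gene ids of the two matrices; returns
    the full samples_a × samples_b correlation matrix.
    """
    shared = [g for g in cm_a.gene_ids if g in set(cm_b.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    ia = [cm_a.gene_ids.index(g) for g in shared]
    ib = {g: i for i, g in enumerate(cm_b.gene_ids)}
    ibx = [ib[g] for g in shared]
    la = np.log2(cm_a.matrix(which)[ia].astype(float) + pseudocount)
    lb = np.log2(cm_b.matrix(which)[ibx].astype(float) + pseudocount)
    out = np.zeros((la.shape[1], lb.shape[1]))
    for i in range(la.shape[1]):
        for j in range(lb.shape[1]):
            x, y = la[:, i], lb[:, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                out[i, j] = np.nan
            else:
                out[i, j] = np.corrcoef(x, y)[0, 1]
    return pd.DataFrame(out, index=cm_a.sample_ids, columns=cm_b.sample_ids)


@dataclass
class QCReport:
    """Bundle of all QC metrics for one library."""

    category_fractions: pd.DataFrame
    mt_rrna_fraction: pd.Series
    detected: pd.DataFrame
    umi_duplication: pd.Series
    correlation: pd.DataFrame
    coverage_norm: np.ndarray
    coverage_raw: np.ndarray

    def to_dict(self) -> dict:
        return {
            "category_fractions": self.category_fractions.to_dict(orient="index"),
            "mt_rrna_fraction": self.mt_rrna_fraction.to_dict(),
            "detected_genes": {
                sid: {str(t): int(v) for t, v in row.items()}
                for sid, row in self.detected.iterrows()
            },
            "umi_duplication": self.umi_duplication.to_dict(),
            "sample_correlation": self.correlation.to_dict(orient="index"),
            "gene_body_coverage": {
                "normalized": [float(x) for x in self.coverage_norm],
                "raw": [int(x) for x in self.coverage_raw],
            },
        }

    def write_json(self, path) -> None:
        with atomic_write(path) as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_coverage_tsv(self, path) -> None:
        with atomic_write(path) as fh:
            fh.write("bin\tnormalized\traw\n")
            for i, (n, r) in enumerate(zip(self.coverage_norm, self.coverage_raw)):
                fh.write(f"{i}\t{n:.6g}\t{int(r)}\n")


def qc_report(
    aln_path,
    gm: GeneModel,
    bs: BarcodeSet,
    rs=None,
    r1_path=None,
    strand_mode: str = "forward",
    max_mismatch: int = 0,
    mt_gene_names: Sequence[str] = DEFAULT_MT_GENES,
    thresholds: Sequence[int] = (0, 1, 5, 10),
    bins: int = 100,
    min_gene_len: int = 100,
) -> Tuple[QCReport, CountMatrices]:
    """Run the full QC battery over one alignment file."""
    from .quant import build_count_matrices

    cat_counts = pd.DataFrame(
        0, index=list(bs.sample_ids), columns=list(CATEGORIES), dtype=np.int64
    )
    feature_records = []
    raw = np.zeros(bins, dtype=np.int64)
    for sid, umi, outcome, rec in classify_alignments(
        aln_path, gm, bs, rs=rs, r1_path=r1_path,
        strand_mode=strand_mode, max_mismatch=max_mismatch,
    ):
        cat_counts.loc[sid, outcome.category] += 1
        if outcome.category != "feature":
            continue
        feature_records.append((sid, umi, outcome.gene_id))
        gene = gm.genes[outcome.gene_id]
        L = gene.spliced_length
        if L < min_gene_len:
            continue
        for gs, ge in rec.get_blocks():
            for sp_a, sp_b in gene.genomic_to_spliced_intervals(gs, ge):
                pos = np.arange(sp_a, sp_b, dtype=np.int64)
                raw += np.bincount(pos * bins // L, minlength=bins)
    cm = build_count_matrices(feature_records, gm, bs)
    peak = raw.max()
    norm = raw / peak if peak > 0 else np.zeros(bins, dtype=float)
    report = QCReport(
        category_fractions=category_fractions(cat_counts),
        mt_rrna_fraction=mt_fraction(cm, gm, mt_gene_names),
        detected=detected_genes(cm, thresholds),
        umi_duplication=umi_duplication(cm),
        correlation=correlate_log_counts(cm, cm),
        coverage_norm=norm,
        coverage_raw=raw,
    )
    return report, cm
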