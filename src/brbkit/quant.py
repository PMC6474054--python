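"""Gene-level read and UMI counting from aligned 3'-tag cDNA reads.

The counting contract mirrors the classic union-mode annotation step of
tag-based RNA-seq pipelines: a read counts for a gene when the union of
genes overlapped by its aligned blocks (CIGAR M/=/X segments, introns
skipped) contains exactly that gene and the strand is compatible. Reads
overlapping no gene are ``no_feature``, more than one gene ``ambiguous``;
secondary/supplementary records or NH>1 are ``multimapped``; unmapped reads
keep their own category.

Two matrices are produced per run: raw read counts, and molecule (UMI)
counts obtained by collapsing reads with identical UMI strings per
(sample, gene). UMIs containing 'N' are kept for read counting but excluded
from molecule counting. ``umis <= reads`` holds cell-wise by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse
from intervaltree import IntervalTree

from ._utils import as_line_stream, atomic_write
from .demux import BarcodeSet, ReadStructure, extract_tag, match_barcode, parse_tagged_name

CATEGORIES = ("feature", "no_feature", "ambiguous", "multimapped", "unmapped")


class GtfParseError(ValueError):
    pass


@dataclass(frozen=True)
class Gene:
    """One gene: strand-aware merged exon intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    gene_name: Optional[str] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"gene {self.gene_id}: exons not sorted/merged")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def _offsets(self) -> List[int]:
        # cumulative spliced offset of each exon start (plus-sense)
        off, out = 0, []
        for s, e in self.exons:
            out.append(off)
            off += e - s
        return out

    def genomic_to_spliced_intervals(
        self, gs: int, ge: int
    ) -> List[Tuple[int, int]]:
        """Project a genomic interval onto 5'→3' spliced coordinates.

        Portions outside the merged exons are dropped. For minus-strand
        genes the spliced axis runs right-to-left along the genome.
        """
        L = self.spliced_length
        out = []
        for (s, e), off in zip(self.exons, self._offsets()):
            a, b = max(gs, s), min(ge, e)
            if a >= b:
                continue
            sp_a, sp_b = off + a - s, off + b - s
            if self.strand == "-":
                sp_a, sp_b = L - sp_b, L - sp_a
            out.append((sp_a, sp_b))
        return out

    def spliced_to_genomic_blocks(self, a: int, b: int) -> List[Tuple[int, int]]:
        """Inverse projection: spliced [a, b) → ascending genomic blocks."""
        if not (0 <= a < b <= self.spliced_length):
            raise ValueError("spliced interval out of range")
        if self.strand == "-":
            a, b = self.spliced_length - b, self.spliced_length - a
        out = []
        for (s, e), off in zip(self.exons, self._offsets()):
            lo, hi = max(a, off), min(b, off + e - s)
            if lo >= hi:
                continue
            out.append((s + lo - off, s + hi - off))
        return out


@dataclass
class GeneModel:
    """All genes of an annotation plus a per-chromosome interval index."""

    genes: Dict[str, Gene]
    gene_order: List[str]
    chrom_lengths: Dict[str, int] = field(default_factory=dict)
    _trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._trees:
            for g in self.genes.values():
                tree = self._trees.setdefault(g.chrom, IntervalTree())
                for s, e in g.exons:
                    tree[s:e] = g.gene_id

    @classmethod
    def from_genes(cls, genes: Sequence[Gene], chrom_lengths=None) -> "GeneModel":
        return cls(
            genes={g.gene_id: g for g in genes},
            gene_order=[g.gene_id for g in genes],
            chrom_lengths=dict(chrom_lengths or {}),
        )

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def name_to_ids(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for gid in self.gene_order:
            name = self.genes[gid].gene_name or gid
            out.setdefault(name, []).append(gid)
        return out

    def __len__(self) -> int:
        return len(self.genes)


def _merge_intervals(ivs: List[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Merge overlapping or adjacent intervals."""
    ivs = sorted(ivs)
    out: List[List[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def _parse_gtf_attrs(attr: str) -> Dict[str, str]:
    out = {}
    for part in attr.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def load_gene_model(
    source, feature_type: str = "exon", id_attr: str = "gene_id"
) -> GeneModel:
    """Parse a GTF into a :class:`GeneModel`.

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open; overlapping or adjacent exons of one gene are merged.
    Parse errors report the offending line number.
    """
    per_gene: Dict[str, dict] = {}
    order: List[str] = []
    stream = as_line_stream(source)
    try:
        for lineno, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feat, start, end, _score, strand, _frame, attrs = fields[:9]
            if feat != feature_type:
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if e1 < s1:
                raise GtfParseError(f"line {lineno}: end < start ({e1} < {s1})")
            ad = _parse_gtf_attrs(attrs)
            gid = ad.get(id_attr)
            if gid is None:
                raise GtfParseError(f"line {lineno}: missing attribute {id_attr!r}")
            rec = per_gene.get(gid)
            if rec is None:
                per_gene[gid] = rec = {
                    "chrom": chrom,
                    "strand": strand,
                    "name": ad.get("gene_name"),
                    "exons": [],
                }
                order.append(gid)
            elif rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfParseError(
                    f"line {lineno}: gene {gid} spans multiple chromosomes or strands"
                )
            rec["exons"].append((s1 - 1, e1))
            if rec["name"] is None and ad.get("gene_name"):
                rec["name"] = ad["gene_name"]
    finally:
        if hasattr(stream, "close"):
            stream.close()
    genes = [
        Gene(
            gene_id=gid,
            chrom=per_gene[gid]["chrom"],
            strand=per_gene[gid]["strand"],
            exons=_merge_intervals(per_gene[gid]["exons"]),
            gene_name=per_gene[gid]["name"],
        )
        for gid in order
    ]
    return GeneModel.from_genes(genes)


@dataclass(frozen=True)
class AssignOutcome:
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "feature") != (self.gene_id is not None):
            raise ValueError("gene_id set iff category == 'feature'")


def assign_read(
    aln: pysam.AlignedSegment,
    gm: GeneModel,
    strand_mode: str = "forward",
) -> AssignOutcome:
    """Classify one alignment record against the gene model (union mode)."""
    if strand_mode not in ("forward", "reverse", "unstranded"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if aln.is_unmapped:
        return AssignOutcome("unmapped")
    if aln.is_secondary or aln.is_supplementary:
        return AssignOutcome("multimapped")
    if aln.has_tag("NH") and aln.get_tag("NH") > 1:
        return AssignOutcome("multimapped")
    read_strand = "-" if aln.is_reverse else "+"
    hits: set = set()
    chrom = aln.reference_name
    for bs_, be_ in aln.get_blocks():
        hits |= gm.overlapping_genes(chrom, bs_, be_)
    if strand_mode != "unstranded":
        want = read_strand if strand_mode == "forward" else ("-" if read_strand == "+" else "+")
        hits = {gid for gid in hits if gm.genes[gid].strand == want}
    if not hits:
        return AssignOutcome("no_feature")
    if len(hits) > 1:
        return AssignOutcome("ambiguous")
    return AssignOutcome("feature", hits.pop())


@dataclass
class CountMatrices:
    """Paired genes × samples integer matrices: raw reads and UMIs."""

    gene_ids: List[str]
    sample_ids: List[str]
    reads: np.ndarray
    umis: np.ndarray

    def __post_init__(self):
        self.reads = np.asarray(self.reads, dtype=np.int64)
        self.umis = np.asarray(self.umis, dtype=np.int64)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.reads.shape != shape or self.umis.shape != shape:
            raise ValueError("matrix shapes inconsistent with gene/sample orders")
        if (self.reads < 0).any() or (self.umis < 0).any():
            raise ValueError("negative counts")
        if (self.umis > self.reads).any():
            raise ValueError("umis > reads in some cell")

    def reads_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.reads, index=self.gene_ids, columns=self.sample_ids)

    def umis_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.umis, index=self.gene_ids, columns=self.sample_ids)

    def matrix(self, which: str) -> np.ndarray:
        if which not in ("reads", "umis"):
            raise ValueError(f"unknown matrix {which!r}")
        return self.reads if which == "reads" else self.umis


def build_count_matrices(
    records: Iterable[Tuple[str, str, str]],
    gm: GeneModel,
    bs: BarcodeSet,
) -> CountMatrices:
    """Tally feature-assigned records ``(sample_id, umi, gene_id)``.

    Read counts are raw record counts; UMI counts are distinct UMI strings
    per (gene, sample), excluding UMIs containing 'N'. Genes or samples
    with no records keep explicit zero rows/columns.
    """
    gi = {g: i for i, g in enumerate(gm.gene_order)}
    si = {s: j for j, s in enumerate(bs.sample_ids)}
    reads = np.zeros((len(gi), len(si)), dtype=np.int64)
    umi_sets: Dict[Tuple[int, int], set] = {}
    for sid, umi, gid in records:
        if sid not in si:
            raise ValueError(f"unknown sample id {sid!r}")
        if gid not in gi:
            raise ValueError(f"unknown gene id {gid!r}")
        cell = (gi[gid], si[sid])
        reads[cell] += 1
        if umi and "N" not in umi:
            umi_sets.setdefault(cell, set()).add(umi)
    umis = np.zeros_like(reads)
    for cell, s in umi_sets.items():
        umis[cell] = len(s)
    return CountMatrices(list(gm.gene_order), list(bs.sample_ids), reads, umis)


def load_r1_tag_map(r1_path, rs: ReadStructure) -> Dict[str, Tuple[str, str]]:
    """Map read id → (barcode, umi) from the tag-read FASTQ."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    from ._utils import open_maybe_gzip

    out: Dict[str, Tuple[str, str]] = {}
    with open_maybe_gzip(r1_path, "rt") as fh:
        for title, seq, _q in FastqGeneralIterator(fh):
            tag = extract_tag(seq, rs)
            if tag is not None:
                out[title.split()[0].removesuffix("/1")] = tag
    return out


def classify_alignments(
    aln_path,
    gm: GeneModel,
    bs: BarcodeSet,
    rs: Optional[ReadStructure] = None,
    r1_path=None,
    strand_mode: str = "forward",
    max_mismatch: int = 0,
) -> Iterator[Tuple[Optional[str], str, AssignOutcome, pysam.AlignedSegment]]:
    """Stream (sample_id, umi, outcome, record) over an alignment file.

    The sample and UMI come either from the ``_BARCODE_UMI`` suffix of the
    read name (demultiplexed input) or, when ``r1_path`` is given, from the
    matching tag read. Secondary and supplementary records are skipped so
    every query name is classified exactly once.
    """
    tag_map = load_r1_tag_map(r1_path, rs) if r1_path is not None else None
    save = pysam.set_verbosity(0)
    try:
        af = pysam.AlignmentFile(str(aln_path), check_sq=False)
    finally:
        pysam.set_verbosity(save)
    with af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            qname = rec.query_name
            if tag_map is not None:
                tag = tag_map.get(qname)
                if tag is None:
                    continue
                barcode, umi = tag
            else:
                _orig, barcode, umi = parse_tagged_name(qname)
            sid, _reason = match_barcode(barcode, bs, max_mismatch)
            if sid is None:
                continue
            yield sid, umi, assign_read(rec, gm, strand_mode), rec


def count_alignments(
    aln_path,
    gm: GeneModel,
    bs: BarcodeSet,
    rs: Optional[ReadStructure] = None,
    r1_path=None,
    strand_mode: str = "forward",
    max_mismatch: int = 0,
) -> Tuple[CountMatrices, pd.DataFrame]:
    """Full counting step: classify every read, build both matrices.

    Returns the matrices and a per-sample category-count table
    (samples × feature/no_feature/ambiguous/multimapped/unmapped).
    """
    cat_counts = pd.DataFrame(
        0, index=list(bs.sample_ids), columns=list(CATEGORIES), dtype=np.int64
    )
    feature_records = []
    for sid, umi, outcome, _rec in classify_alignments(
        aln_path, gm, bs, rs=rs, r1_path=r1_path,
        strand_mode=strand_mode, max_mismatch=max_mismatch,
    ):
        cat_counts.loc[sid, outcome.category] += 1
        if outcome.category == "feature":
            feature_records.append((sid, umi, outcome.gene_id))
    cm = build_count_matrices(feature_records, gm, bs)
    return cm, cat_counts


def write_matrix(cm: CountMatrices, path, which: str = "reads", format: str = "tsv"):
    """Write one matrix as TSV (dense) or MatrixMarket (sparse + sidecars).

    TSV: genes as rows, first column ``gene_id``, samples as columns.
    MTX: coordinate integer file plus ``<stem>.genes.tsv`` and
    ``<stem>.samples.tsv`` sidecars. Both round-trip losslessly through
    :func:`read_matrix`.
    """
    mat = cm.matrix(which)
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(mat, index=cm.gene_ids, columns=cm.sample_ids)
        df.index.name = "gene_id"
        with atomic_write(path) as fh:
            df.to_csv(fh, sep="\t")
    elif format == "mtx":
        sp = scipy.sparse.coo_matrix(mat)
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), sp, field="integer")
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        with atomic_write(f"{stem}.genes.tsv") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with atomic_write(f"{stem}.samples.tsv") as fh:
            fh.write("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix(path, format: str = "tsv") -> Tuple[List[str], List[str], np.ndarray]:
    """Read back a matrix written by :func:`write_matrix`."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return list(df.index), list(df.columns), df.to_numpy(dtype=np.int64)
    if format == "mtx":
        mat = scipy.io.mmread(str(path)).toarray().astype(np.int64)
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        genes = Path(f"{stem}.genes.tsv").read_text().splitlines()
        samples = Path(f"{stem}.samples.tsv").read_text().splitlines()
        return genes, samples, mat
    raise ValueError(f"unknown format {format!r}")


def write_count_log(cat_counts: pd.DataFrame, path) -> None:
    """Persist the per-sample category tallies as JSON."""
    with atomic_write(path) as fh:
        json.dump(
            {sid: {c: int(v) for c, v in row.items()} for sid, row in cat_counts.iterrows()},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
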