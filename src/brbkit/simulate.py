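"""Fully synthetic early-multiplexed 3'-tag RNA-seq runs with known truth.

The generator emulates the computational signature of a barcoded oligo-dT
library: read 1 carries sample barcode + UMI (random N bases followed by
non-T V bases), read 2 a cDNA fragment whose start is 3'-biased along the
spliced gene body; PCR duplication re-reads each molecule a geometric
number of times; configurable fractions of reads are made unmapped,
multimapped (NH=2) or intergenic; sequencing errors are injected per base.
Transcript sequence is synthetic random DNA — the SAM positions and CIGARs,
not sequence homology, carry the ground truth.

Everything is seeded: the same configuration yields byte-identical FASTQ
and SAM files, and the per-read bookkeeping provides exact expected read
and UMI matrices for end-to-end pipeline tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from ._utils import atomic_write
from .demux import BarcodeSet, ReadStructure, hamming
from .quant import GeneModel, load_gene_model

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_barcodes(
    n: int, length: int = 6, min_dist: int = 3, seed: int = 0
) -> BarcodeSet:
    """Draw ``n`` ACGT barcodes with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chosen: List[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("cannot place barcodes at the requested distance")
        bc = "".join(rng.choice(bases, size=length))
        if all(hamming(bc, c) >= min_dist for c in chosen):
            chosen.append(bc)
    return BarcodeSet.from_pairs([(f"s{i+1}", bc) for i, bc in enumerate(chosen)])


@dataclass
class ToyAnnotation:
    gtf: str
    chrom_lengths: Dict[str, int]

    def write(self, path) -> None:
        with atomic_write(path) as fh:
            fh.write(self.gtf)

    def gene_model(self) -> GeneModel:
        gm = load_gene_model(self.gtf)
        gm.chrom_lengths = dict(self.chrom_lengths)
        return gm


def make_toy_annotation(
    n_genes: int = 20,
    n_chroms: int = 2,
    exons_per_gene: Tuple[int, int] = (1, 3),
    exon_len: Tuple[int, int] = (100, 400),
    intron_len: Tuple[int, int] = (60, 300),
    intergenic_gap: Tuple[int, int] = (200, 500),
    include_mt: bool = False,
    seed: int = 0,
) -> ToyAnnotation:
    """Generate a deterministic toy GTF with non-overlapping multi-exon genes.

    Genes are laid out sequentially per chromosome with intergenic gaps and
    random strands; ``include_mt`` appends two genes named MT-RNR1 and
    MT-RNR2 on a contig called MT. Chromosome lengths leave a gene-free
    tail so intergenic reads can be simulated.
    """
    rng = np.random.default_rng(seed)
    lines: List[str] = []
    chrom_lengths: Dict[str, int] = {}
    cursors = {f"chr{c+1}": 0 for c in range(n_chroms)}

    def emit_gene(gid: str, gname: str, chrom: str, cursor: int) -> int:
        strand = rng.choice(["+", "-"])
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        pos = cursor + int(rng.integers(*intergenic_gap))
        exons = []
        for k in range(n_ex):
            if k:
                pos += int(rng.integers(*intron_len))
            length = int(rng.integers(*exon_len))
            exons.append((pos, pos + length))
            pos += length
        start1, end1 = exons[0][0] + 1, exons[-1][1]
        attrs = f'gene_id "{gid}"; gene_name "{gname}";'
        lines.append(
            f"{chrom}\ttoy\tgene\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}"
        )
        for s, e in exons:
            lines.append(f"{chrom}\ttoy\texon\t{s+1}\t{e}\t.\t{strand}\t.\t{attrs}")
        return pos

    chroms = list(cursors)
    for i in range(n_genes):
        chrom = chroms[i % n_chroms]
        gid = f"G{i:04d}"
        cursors[chrom] = emit_gene(gid, gid, chrom, cursors[chrom])
    for chrom in chroms:
        chrom_lengths[chrom] = cursors[chrom] + 2000
    if include_mt:
        mt_cursor = 0
        for j, name in enumerate(("MT-RNR1", "MT-RNR2")):
            mt_cursor = emit_gene(f"GMT{j:02d}", name, "MT", mt_cursor)
        chrom_lengths["MT"] = mt_cursor + 2000
    return ToyAnnotation(gtf="\n".join(lines) + "\n", chrom_lengths=chrom_lengths)


@dataclass
class SimLibraryConfig:
    """All knobs of one simulated library run.

    ``molecule_matrix`` (genes × samples) fixes the true molecule counts;
    when absent, each sample gets ``molecules_per_sample`` molecules spread
    over genes with log-normal weights. ``dup_p`` is the success
    probability of the geometric PCR duplication factor (mean 1/dup_p
    reads per molecule). ``three_prime_decay`` is the exponential scale, in
    transcript bases, of the fragment-end distance from the 3' terminus.
    """

    barcodes: BarcodeSet
    read_structure: ReadStructure
    molecule_matrix: Optional[pd.DataFrame] = None
    molecules_per_sample: int = 1000
    gene_weight_sigma: float = 1.0
    dup_p: float = 0.5
    error_rate: float = 0.0
    barcode_error_rate: float = 0.0
    frac_unmapped: float = 0.0
    frac_multimapped: float = 0.0
    frac_intergenic: float = 0.0
    three_prime_decay: float = 100.0
    read_len: int = 50
    shuffle: bool = True
    seed: int = 0

    def validate(self, gm: GeneModel) -> None:
        fr = (self.frac_unmapped, self.frac_multimapped, self.frac_intergenic)
        if any(not (0.0 <= f <= 1.0) for f in fr) or sum(fr) > 1.0:
            raise ValueError("special-read fractions must be in [0,1] and sum <= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 < self.dup_p <= 1.0):
            raise ValueError("dup_p must be in (0, 1]")
        if self.molecule_matrix is not None:
            unknown_g = set(self.molecule_matrix.index) - set(gm.gene_order)
            if unknown_g:
                raise ValueError(f"molecule matrix has unknown genes: {sorted(unknown_g)[:5]}")
            unknown_s = set(self.molecule_matrix.columns) - set(self.barcodes.sample_ids)
            if unknown_s:
                raise ValueError(f"molecule matrix has unknown samples: {sorted(unknown_s)}")


@dataclass
class GroundTruth:
    """Per-read and per-molecule bookkeeping of a simulated run."""

    reads: pd.DataFrame  # read_id, sample, gene, umi, category
    molecules: pd.DataFrame  # sample, gene, umi, dup_factor, n_gene_reads
    expected_reads: pd.DataFrame  # genes × samples
    expected_umis: pd.DataFrame

    def write(self, outdir, config_echo: Optional[dict] = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with atomic_write(outdir / "truth_reads.tsv") as fh:
            self.reads.to_csv(fh, sep="\t", index=False)
        with atomic_write(outdir / "truth_molecules.tsv") as fh:
            self.molecules.to_csv(fh, sep="\t", index=False)
        for name, df in (
            ("truth_expected_reads.tsv", self.expected_reads),
            ("truth_expected_umis.tsv", self.expected_umis),
        ):
            with atomic_write(outdir / name) as fh:
                df.to_csv(fh, sep="\t", index_label="gene_id")
        if config_echo is not None:
            with atomic_write(outdir / "sim_config.json") as fh:
                json.dump(config_echo, fh, indent=2, sort_keys=True, default=str)
                fh.write("\n")


@dataclass
class SimulatedLibrary:
    r1_path: Path
    r2_path: Path
    sam_path: Path
    truth: GroundTruth


def _draw_molecule_matrix(
    cfg: SimLibraryConfig, gm: GeneModel, rng: np.random.Generator
) -> pd.DataFrame:
    if cfg.molecule_matrix is not None:
        full = pd.DataFrame(
            0, index=list(gm.gene_order), columns=list(cfg.barcodes.sample_ids)
        )
        mm = cfg.molecule_matrix
        full.loc[mm.index, mm.columns] = mm.astype(int)
        return full
    genes = list(gm.gene_order)
    weights = rng.lognormal(mean=0.0, sigma=cfg.gene_weight_sigma, size=len(genes))
    weights /= weights.sum()
    data = {
        sid: rng.multinomial(cfg.molecules_per_sample, weights)
        for sid in cfg.barcodes.sample_ids
    }
    return pd.DataFrame(data, index=genes)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def _cigar_from_blocks(blocks: List[Tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _intergenic_spots(gm: GeneModel, read_len: int) -> Dict[str, int]:
    """One gene-free position per chromosome (in the tail after all genes)."""
    spots = {}
    for chrom, length in gm.chrom_lengths.items():
        last = 0
        for g in gm.genes.values():
            if g.chrom == chrom:
                last = max(last, g.end)
        pos = last + 100
        if pos + read_len < length:
            spots[chrom] = pos
    return spots


def simulate_brbseq_library(
    cfg: SimLibraryConfig, gm: GeneModel, outdir
) -> SimulatedLibrary:
    """Generate R1/R2 FASTQ, an aligned SAM, and the full ground truth.

    See the module docstring for the generative model. Raises before any
    file is written when the configuration is inconsistent with the gene
    model.
    """
    cfg.validate(gm)
    if not gm.chrom_lengths:
        raise ValueError("gene model needs chrom_lengths to emit a SAM header")
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mol_matrix = _draw_molecule_matrix(cfg, gm, rng)
    intergenic = _intergenic_spots(gm, cfg.read_len)
    if cfg.frac_intergenic > 0 and not intergenic:
        raise ValueError("no gene-free space available for intergenic reads")
    chroms = sorted(gm.chrom_lengths)

    # synthetic transcript per gene (spliced sequence, 5'->3')
    bases = np.array(list("ACGT"))
    transcripts = {
        gid: "".join(rng.choice(bases, size=max(gm.genes[gid].spliced_length, 1)))
        for gid in gm.gene_order
    }

    rs = cfg.read_structure
    sample_barcode = dict(cfg.barcodes.entries)
    n_special = (cfg.frac_unmapped, cfg.frac_multimapped, cfg.frac_intergenic)

    reads_rows = []  # (sample, gene, umi, category)
    mol_rows = []  # (sample, gene, umi, dup_factor, n_gene_reads)
    r1_recs: List[Tuple[str, str]] = []
    r2_recs: List[Tuple[str, str]] = []
    sam_recs: List[dict] = []

    for sid in cfg.barcodes.sample_ids:
        barcode = sample_barcode[sid]
        for gid in gm.gene_order:
            n_mol = int(mol_matrix.loc[gid, sid])
            if n_mol == 0:
                continue
            gene = gm.genes[gid]
            tx = transcripts[gid]
            L = len(tx)
            rl = min(cfg.read_len, L)
            for _ in range(n_mol):
                umi_n = "".join(rng.choice(bases, size=rs.umi_n_len))
                umi_v = "".join(rng.choice(bases[:3], size=rs.umi_v_len))  # A,C,G only
                umi = umi_n + umi_v
                dup = int(rng.geometric(cfg.dup_p))
                n_gene_reads = 0
                for _r in range(dup):
                    u = rng.random()
                    if u < n_special[0]:
                        category = "unmapped"
                    elif u < n_special[0] + n_special[1]:
                        category = "multimapped"
                    elif u < sum(n_special):
                        category = "intergenic"
                    else:
                        category = "gene"
                        n_gene_reads += 1
                    # fragment placement: distance of the 3' read end from
                    # the transcript 3' terminus ~ Exp(decay), clipped
                    off = min(int(rng.exponential(cfg.three_prime_decay)), L - rl)
                    a, b = L - rl - off, L - off
                    read_seq = _mutate(tx[a:b], cfg.error_rate, rng)

                    r1_seq = barcode + umi
                    if cfg.barcode_error_rate > 0 and rng.random() < cfg.barcode_error_rate:
                        i = int(rng.integers(rs.barcode_len))
                        repl = rng.choice([x for x in "ACGT" if x != r1_seq[i]])
                        r1_seq = r1_seq[:i] + repl + r1_seq[i + 1 :]

                    if category == "unmapped":
                        sam = {"flag": 4}
                    elif category == "intergenic":
                        chrom = chroms[int(rng.integers(len(chroms)))]
                        while chrom not in intergenic:
                            chrom = chroms[int(rng.integers(len(chroms)))]
                        sam = {
                            "flag": 0,
                            "chrom": chrom,
                            "pos": intergenic[chrom],
                            "cigar": f"{rl}M",
                            "seq": read_seq,
                        }
                    else:
                        blocks = gene.spliced_to_genomic_blocks(a, b)
                        genome_seq = (
                            _revcomp(read_seq) if gene.strand == "-" else read_seq
                        )
                        sam = {
                            "flag": 16 if gene.strand == "-" else 0,
                            "chrom": gene.chrom,
                            "pos": blocks[0][0],
                            "cigar": _cigar_from_blocks(blocks),
                            "seq": genome_seq,
                        }
                        if category == "multimapped":
                            sam["nh"] = 2
                    reads_rows.append((sid, gid, umi, category))
                    r1_recs.append((r1_seq, "I" * len(r1_seq)))
                    r2_recs.append((read_seq, "I" * len(read_seq)))
                    sam_recs.append(sam)
                mol_rows.append((sid, gid, umi, dup, n_gene_reads))

    n_reads = len(reads_rows)
    order = rng.permutation(n_reads) if cfg.shuffle else np.arange(n_reads)
    read_ids = [f"r{i:08d}" for i in range(n_reads)]

    reads_df = pd.DataFrame(
        [(read_ids[k],) + reads_rows[order[k]] for k in range(n_reads)],
        columns=["read_id", "sample", "gene", "umi", "category"],
    )
    molecules_df = pd.DataFrame(
        mol_rows, columns=["sample", "gene", "umi", "dup_factor", "n_gene_reads"]
    )

    # expected matrices: gene-category reads only; UMIs distinct per cell
    genes, samples = list(gm.gene_order), list(cfg.barcodes.sample_ids)
    exp_reads = pd.DataFrame(0, index=genes, columns=samples)
    gene_reads = reads_df[reads_df["category"] == "gene"]
    tally = gene_reads.groupby(["gene", "sample"]).size()
    for (g, s), v in tally.items():
        exp_reads.loc[g, s] = v
    exp_umis = pd.DataFrame(0, index=genes, columns=samples)
    utally = gene_reads.groupby(["gene", "sample"])["umi"].nunique()
    for (g, s), v in utally.items():
        exp_umis.loc[g, s] = v

    truth = GroundTruth(
        reads=reads_df,
        molecules=molecules_df,
        expected_reads=exp_reads,
        expected_umis=exp_umis,
    )

    r1_path = outdir / "sim.R1.fastq"
    r2_path = outdir / "sim.R2.fastq"
    sam_path = outdir / "sim.sam"
    with atomic_write(r1_path) as f1, atomic_write(r2_path) as f2:
        for k in range(n_reads):
            seq1, q1 = r1_recs[order[k]]
            seq2, q2 = r2_recs[order[k]]
            f1.write(f"@{read_ids[k]}\n{seq1}\n+\n{q1}\n")
            f2.write(f"@{read_ids[k]}\n{seq2}\n+\n{q2}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(gm.chrom_lengths[c])} for c in chroms],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        hdr = out.header
        for k in range(n_reads):
            rec_info = sam_recs[order[k]]
            a = pysam.AlignedSegment(hdr)
            a.query_name = read_ids[k]
            a.flag = rec_info["flag"]
            if rec_info["flag"] & 4:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = hdr.get_tid(rec_info["chrom"])
                a.reference_start = rec_info["pos"]
                a.cigarstring = rec_info["cigar"]
                a.mapping_quality = 255
                seq = rec_info["seq"]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                if "nh" in rec_info:
                    a.set_tag("NH", rec_info["nh"])
            out.write(a)

    truth.write(outdir, config_echo=_config_echo(cfg))
    return SimulatedLibrary(r1_path=r1_path, r2_path=r2_path, sam_path=sam_path, truth=truth)


def _config_echo(cfg: SimLibraryConfig) -> dict:
    echo = {
        "read_structure": str(cfg.read_structure),
        "samples": list(cfg.barcodes.sample_ids),
        "barcodes": list(cfg.barcodes.barcodes),
    }
    for key in (
        "molecules_per_sample", "gene_weight_sigma", "dup_p", "error_rate",
        "barcode_error_rate", "frac_unmapped", "frac_multimapped",
        "frac_intergenic", "three_prime_decay", "read_len", "shuffle", "seed",
    ):
        echo[key] = getattr(cfg, key)
    return echo
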