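# brbkit

A post-sequencing toolkit for **early-multiplexed 3'-end bulk RNA-seq**
(BRB-seq-style libraries). In these protocols every sample is tagged at
reverse transcription with a barcoded oligo-dT primer, so one pooled
library serves dozens of samples: read 1 carries only the sample barcode
and a UMI (layout `B6N10V5`: 6 nt barcode, 10 random `N` bases, 5 random
non-T `V` bases), read 2 carries the cDNA fragment. brbkit covers every
step between the aligner and the statistics:

* **demux** — split pooled R1/R2 FASTQ into per-sample cDNA FASTQs by
  barcode (Hamming tolerance with strict tie handling), extracting UMIs
  into the read names; optional adapter/poly-A trimming.
* **quant** — union-mode, strand-aware gene assignment of aligned reads
  against a GTF, producing paired genes × samples **read** and **UMI**
  count matrices (TSV or MatrixMarket), with `umis ≤ reads` guaranteed.
* **qc** — alignment-category fractions, MT-rRNA contamination
  (MT-RNR1/MT-RNR2), detected genes per threshold, UMI-based duplication
  `1 − ΣUMI/Σreads`, 5'→3' gene-body coverage in spliced coordinates, and
  log-scale sample correlation.
* **downsample** — seeded uniform downsampling of SAM/BAM to an exact
  distinct-read count, with replicate generation and manifests, for
  depth-matched protocol comparisons.
* **evalsim** — scoring of DE result tables against a self-assigned gold
  standard (positives: |FC| ≥ 2, FDR ≤ 0.05 in the reference): empirical
  power, ROC/PR curves swept over every ranked p-value cutoff, the
  analytic depth needed to detect a gene of given CPM
  (D = ⌈ln(1−p)/ln(1−cpm/10⁶)⌉), plus a negative-binomial count simulator
  and moment-based two-group test for power curves over replicate numbers.
* **simulate** — a fully synthetic library generator (toy GTF, barcoded
  R1, cDNA R2, aligned SAM with spliced CIGARs, PCR duplicates, 3'-biased
  coverage, injected errors) with exact per-read ground truth, so the
  whole pipeline is testable end to end without external data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from brbkit import *
from brbkit.simulate import (SimLibraryConfig, make_toy_annotation,
                             random_barcodes, simulate_brbseq_library)

anno = make_toy_annotation(n_genes=50, include_mt=True, seed=0)
gm = anno.gene_model()
bs = random_barcodes(4, length=6, min_dist=3, seed=0)
rs = parse_read_structure("B6N10V5")
cfg = SimLibraryConfig(barcodes=bs, read_structure=rs,
                       molecules_per_sample=2000, dup_p=0.5, seed=0)
lib = simulate_brbseq_library(cfg, gm, "example")

summary = demultiplex(lib.r1_path, lib.r2_path, bs, rs, "example/demux")
print("assigned:", dict(summary.per_sample))

cm, cats = count_alignments(lib.sam_path, gm, bs, rs=rs, r1_path=lib.r1_path)
print("reads == truth:", (cm.reads_df().values == lib.truth.expected_reads.values).all())
print("umis  == truth:", (cm.umis_df().values == lib.truth.expected_umis.values).all())
print("umi duplication:", umi_duplication(cm).round(3).to_dict())

pc = power_curve(replicate_levels=(5, 20), n_sims=10, n_genes=1000, seed=0)
print(pc.to_string(index=False))
```

Output:

```
assigned: {'s1': 4036, 's3': 3932, 's4': 3901, 's2': 3978}
reads == truth: True
umis  == truth: True
umi duplication: {'s1': 0.504, 's2': 0.497, 's3': 0.491, 's4': 0.487}
 n_replicates  mean_tpr   sd_tpr  n_sims
            5     0.019 0.028067      10
           20     0.436 0.066198      10
```

Reading it: ~16k reads (2000 molecules/sample × 4 samples × mean
duplication 2) are all assigned to their true samples; counting the
aligned reads reproduces the generator's read and molecule matrices
exactly; the UMI-based duplication estimate (~0.5) matches the geometric
duplication the library was simulated with (mean factor 2 → half the reads
are duplicates); and the simulated power analysis shows the large gain in
true-positive rate from 5 to 20 replicates per group at 10% DE genes.

The same stages are available as a CLI — `brbkit simulate`, `brbkit
demux`, `brbkit count`, `brbkit qc`, `brbkit downsample`, `brbkit eval` —
each writing a `manifest.json` (parameters, input digests, seeds, version)
sufficient to reproduce the run.

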