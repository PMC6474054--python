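"""Seeded uniform downsampling of alignment files.

Depth-matched protocol comparisons require every library to be reduced to
the same number of reads. Downsampling is done at the alignment level,
after mapping and before counting, so that mapping artifacts are not
resampled. The sampling unit is the distinct query name: all records of a
selected read (e.g. secondary alignments) are kept together, record order
is preserved, and a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np
import pysam

from ._utils import atomic_write, file_md5

RNG_NAME = "numpy-PCG64"


@dataclass(frozen=True)
class DownsampleSpec:
    target_n: int
    seed: int
    replicates: int = 1

    def __post_init__(self):
        if self.target_n < 0:
            raise ValueError("target_n must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _open_aln(path, mode="r", template=None, header=None):
    save = pysam.set_verbosity(0)
    try:
        kwargs = {}
        if template is not None:
            kwargs["template"] = template
        if header is not None:
            kwargs["header"] = header
        if "r" in mode:
            kwargs["check_sq"] = False
        return pysam.AlignmentFile(str(path), mode, **kwargs)
    finally:
        pysam.set_verbosity(save)


def _write_mode(path) -> str:
    return "wb" if str(path).endswith(".bam") else "wh"


def downsample_alignments(in_path, out_path, target_n: int, seed: int) -> dict:
    """Sample exactly ``target_n`` distinct query names, uniformly, without
    replacement.

    Two passes: the first collects distinct names in order of appearance,
    the second emits every record of the selected names in the original
    order. Raises ``ValueError`` when ``target_n`` exceeds the number of
    distinct reads. Returns a manifest dict describing the run.
    """
    names: List[str] = []
    seen = set()
    with _open_aln(in_path) as af:
        for rec in af:
            q = rec.query_name
            if q not in seen:
                seen.add(q)
                names.append(q)
    n_total = len(names)
    if target_n > n_total:
        raise ValueError(
            f"target_n={target_n} exceeds the {n_total} distinct reads available"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(n_total, size=target_n, replace=False) if n_total else []
    chosen = {names[i] for i in chosen_idx}
    with _open_aln(in_path) as af:
        with _open_aln(out_path, _write_mode(out_path), template=af) as out:
            for rec in af:
                if rec.query_name in chosen:
                    out.write(rec)
    manifest = {
        "input": str(in_path),
        "input_md5": file_md5(in_path),
        "output": str(out_path),
        "target_n": int(target_n),
        "n_available": int(n_total),
        "seed": int(seed),
        "rng": RNG_NAME,
    }
    return manifest


def replicate_downsamples(
    in_path, outdir, target_n: int, k: int = 10, base_seed: int = 0
) -> List[dict]:
    """Generate ``k`` independent downsamples; replicate ``i`` uses seed
    ``base_seed + i``.

    Files are named ``rep<i>.sam`` (or ``.bam`` matching the input suffix);
    a ``downsample_manifest.json`` summarising all replicates is written to
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".bam" if str(in_path).endswith(".bam") else ".sam"
    manifests = []
    for i in range(k):
        out = outdir / f"rep{i:02d}{suffix}"
        m = downsample_alignments(in_path, out, target_n, base_seed + i)
        m["replicate"] = i
        manifests.append(m)
    with atomic_write(outdir / "downsample_manifest.json") as fh:
        json.dump(manifests, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifests
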