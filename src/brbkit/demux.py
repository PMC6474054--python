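"""Sample demultiplexing for early-multiplexed 3'-end RNA-seq libraries.

In early-multiplexing protocols every sample is tagged during reverse
transcription with a short sample barcode followed by a unique molecular
identifier (UMI). Read 1 of each pair carries only this tag; read 2 carries
the cDNA fragment. This module models the read-1 tag layout, assigns read
pairs to samples by barcode (with an optional Hamming-distance tolerance),
extracts UMIs, and writes one cDNA FASTQ per sample with the barcode and UMI
appended to the read name so that downstream counting never needs the R1
stream again.

The canonical tag layout is ``B6N10V5``: a 6 nt sample barcode, 10 fully
random bases (N) and 5 random non-T bases (V) that buffer the UMI from the
oligo-dT stretch. UMI length may be zero for UMI-free libraries (``B6``).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._utils import as_line_stream, atomic_write, open_maybe_gzip

UNASSIGNED = None

#: reasons a read pair can fail assignment
REASON_OK = "ok"
REASON_NO_MATCH = "no_match"
REASON_AMBIGUOUS = "ambiguous"
REASON_TOO_SHORT = "too_short"

_STRUCTURE_RE = re.compile(r"^B(\d+)(?:N(\d+))?(?:V(\d+))?$")


class ReadStructureError(ValueError):
    """Malformed read-structure specification."""


class SampleSheetError(ValueError):
    """Invalid barcode sample sheet."""


@dataclass(frozen=True)
class ReadStructure:
    """Layout of the tag read: barcode, then N-segment, then V-segment."""

    barcode_len: int
    umi_n_len: int = 0
    umi_v_len: int = 0

    def __post_init__(self):
        if self.barcode_len < 1:
            raise ReadStructureError("barcode length must be >= 1")
        if self.umi_n_len < 0 or self.umi_v_len < 0:
            raise ReadStructureError("UMI segment lengths must be >= 0")

    @property
    def umi_len(self) -> int:
        return self.umi_n_len + self.umi_v_len

    @property
    def total_len(self) -> int:
        return self.barcode_len + self.umi_len

    def __str__(self) -> str:
        out = f"B{self.barcode_len}"
        if self.umi_n_len:
            out += f"N{self.umi_n_len}"
        if self.umi_v_len:
            out += f"V{self.umi_v_len}"
        return out


def parse_read_structure(spec: str) -> ReadStructure:
    """Parse a compact layout string such as ``"B6N10V5"``.

    Segments must appear in the order B, N, V; N and V are optional.

    >>> parse_read_structure("B6N10V5")
    ReadStructure(barcode_len=6, umi_n_len=10, umi_v_len=5)
    """
    spec = spec.strip().upper()
    m = _STRUCTURE_RE.match(spec)
    if not m:
        # pinpoint the first token that breaks the grammar
        tok = re.match(r"([BNV]\d+)*", spec)
        bad = spec[tok.end():] if tok else spec
        raise ReadStructureError(
            f"malformed read structure {spec!r}: expected B<int>[N<int>][V<int>]"
            + (f", offending token starts at {bad[:4]!r}" if bad else "")
        )
    b, n, v = (int(g) if g else 0 for g in m.groups())
    if b < 1:
        raise ReadStructureError(f"read structure {spec!r} has zero-length barcode")
    return ReadStructure(barcode_len=b, umi_n_len=n, umi_v_len=v)


@dataclass(frozen=True)
class BarcodeSet:
    """Ordered sample-id ↔ barcode mapping with uniform barcode length."""

    entries: Tuple[Tuple[str, str], ...]

    def __post_init__(self):
        if not self.entries:
            raise SampleSheetError("barcode set is empty")
        lengths = {len(bc) for _, bc in self.entries}
        if len(lengths) != 1:
            raise SampleSheetError(f"ragged barcode lengths: {sorted(lengths)}")
        ids = [s for s, _ in self.entries]
        bcs = [b for _, b in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise SampleSheetError(f"duplicate sample ids: {dup}")
        if len(set(bcs)) != len(bcs):
            dup = sorted({b for b in bcs if bcs.count(b) > 1})
            raise SampleSheetError(f"duplicate barcodes: {dup}")
        bad = [b for b in bcs if set(b) - set("ACGT")]
        if bad:
            raise SampleSheetError(f"non-ACGT characters in barcodes: {bad}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "BarcodeSet":
        return cls(tuple((s, b.upper()) for s, b in pairs))

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def barcodes(self) -> list[str]:
        return [b for _, b in self.entries]

    @property
    def barcode_len(self) -> int:
        return len(self.entries[0][1])

    def sample_for(self, barcode: str) -> str:
        for s, b in self.entries:
            if b == barcode:
                return s
        raise KeyError(barcode)

    def __len__(self) -> int:
        return len(self.entries)


def load_sample_sheet(source) -> BarcodeSet:
    """Read a two-column TSV ``sample_id<TAB>barcode`` into a :class:`BarcodeSet`.

    ``source`` may be a path, a file-like object, or the TSV text itself.
    Lines starting with ``#`` are comments. Validation errors report the
    offending line numbers.
    """
    pairs: list[Tuple[str, str]] = []
    seen_bc: dict[str, int] = {}
    seen_id: dict[str, int] = {}
    problems: list[str] = []
    stream = as_line_stream(source)
    try:
        for lineno, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                problems.append(f"line {lineno}: expected sample_id<TAB>barcode")
                continue
            sid, bc = fields[0].strip(), fields[1].strip().upper()
            if set(bc) - set("ACGT"):
                problems.append(f"line {lineno}: non-ACGT barcode {bc!r}")
            if bc in seen_bc:
                problems.append(
                    f"line {lineno}: barcode {bc} duplicates line {seen_bc[bc]}"
                )
            if sid in seen_id:
                problems.append(
                    f"line {lineno}: sample id {sid!r} duplicates line {seen_id[sid]}"
                )
            seen_bc.setdefault(bc, lineno)
            seen_id.setdefault(sid, lineno)
            pairs.append((sid, bc))
    finally:
        if hasattr(stream, "close"):
            stream.close()
    if pairs and len({len(b) for _, b in pairs}) > 1:
        problems.append(
            "barcode lengths are not uniform: "
            + ", ".join(sorted({f"{len(b)} nt" for _, b in pairs}))
        )
    if problems:
        raise SampleSheetError("invalid sample sheet: " + "; ".join(problems))
    if not pairs:
        raise SampleSheetError("sample sheet contains no entries")
    return BarcodeSet(tuple(pairs))


def extract_tag(read1_seq: str, rs: ReadStructure) -> Optional[Tuple[str, str]]:
    """Slice the barcode and UMI off the front of a read-1 sequence.

    Returns ``(barcode, umi)`` uppercased, or ``None`` when the read is
    shorter than the structure's total length.
    """
    if len(read1_seq) < rs.total_len:
        return None
    seq = read1_seq.upper()
    return seq[: rs.barcode_len], seq[rs.barcode_len : rs.total_len]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; 'N' never matches."""
    return sum(x != y for x, y in zip(a, b))


def match_barcode(
    observed: str, bs: BarcodeSet, max_mismatch: int = 0
) -> Tuple[Optional[str], str]:
    """Assign an observed barcode to the uniquely closest known barcode.

    Returns ``(sample_id, "ok")`` when a single barcode is within
    ``max_mismatch`` and strictly closer than every other barcode;
    ``(None, "no_match")`` or ``(None, "ambiguous")`` otherwise. Any 'N' in
    the observed sequence counts as a mismatch against every barcode.
    """
    if len(observed) != bs.barcode_len:
        raise ValueError(
            f"observed barcode length {len(observed)} != set length {bs.barcode_len}"
        )
    observed = observed.upper()
    best_d = best2_d = len(observed) + 1
    best_sid = None
    for sid, bc in bs.entries:
        d = hamming(observed, bc)
        if d < best_d:
            best2_d = best_d
            best_d, best_sid = d, sid
        elif d < best2_d:
            best2_d = d
    if best_d > max_mismatch:
        return UNASSIGNED, REASON_NO_MATCH
    if best2_d == best_d:
        return UNASSIGNED, REASON_AMBIGUOUS
    return best_sid, REASON_OK


def trim_read2(
    seq: str,
    qual: str,
    adapters: Sequence[str] = (),
    polya_min_run: int = 10,
    min_len: int = 20,
) -> Tuple[str, str, bool]:
    """Clip adapter contamination and trailing poly-A from a cDNA read.

    The earliest occurrence of any adapter and everything 3' of it is
    removed first; a trailing A-run of at least ``polya_min_run`` bases is
    then stripped. ``keep`` is False when the surviving read is shorter than
    ``min_len``. Quality is trimmed in lockstep.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence and quality lengths differ")
    upper = seq.upper()
    cut = len(seq)
    for ad in adapters:
        pos = upper.find(ad.upper())
        if pos != -1 and pos < cut:
            cut = pos
    seq, qual, upper = seq[:cut], qual[:cut], upper[:cut]
    run = len(upper) - len(upper.rstrip("A"))
    if run >= polya_min_run:
        seq, qual = seq[: len(seq) - run], qual[: len(qual) - run]
    return seq, qual, len(seq) >= min_len


@dataclass
class DemuxSummary:
    """Bookkeeping of one demultiplexing run."""

    per_sample: Counter = field(default_factory=Counter)
    per_reason: Counter = field(default_factory=Counter)
    total: int = 0

    @property
    def unassigned(self) -> int:
        return self.total - sum(self.per_sample.values())

    def validate(self) -> None:
        assert self.total == self.unassigned + sum(self.per_sample.values())
        assert all(v >= 0 for v in self.per_sample.values())

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "assigned": sum(self.per_sample.values()),
            "unassigned": self.unassigned,
            "per_sample": dict(self.per_sample),
            "per_reason": dict(self.per_reason),
        }

    def write_json(self, path) -> None:
        with atomic_write(path) as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        with atomic_write(path) as fh:
            fh.write("category\tkey\tcount\n")
            for sid, n in self.per_sample.items():
                fh.write(f"sample\t{sid}\t{n}\n")
            for reason, n in sorted(self.per_reason.items()):
                fh.write(f"reason\t{reason}\t{n}\n")
            fh.write(f"total\t-\t{self.total}\n")


class DesynchronizedStreamsError(RuntimeError):
    """R1/R2 read ids disagree or one stream ended early."""


def _read_pairs(r1, r2) -> Iterator[Tuple[int, tuple, tuple]]:
    it1 = FastqGeneralIterator(r1)
    it2 = FastqGeneralIterator(r2)
    idx = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            raise DesynchronizedStreamsError(
                f"streams have unequal record counts (record index {idx})"
            )
        id1 = rec1[0].split()[0].removesuffix("/1")
        id2 = rec2[0].split()[0].removesuffix("/2")
        if id1 != id2:
            raise DesynchronizedStreamsError(
                f"read id mismatch at record index {idx}: {id1!r} vs {id2!r}"
            )
        yield idx, rec1, rec2
        idx += 1


def tag_read_name(name: str, barcode: str, umi: str) -> str:
    """Append the demux tag: ``<original_name>_<BARCODE>_<UMI>``."""
    return f"{name.split()[0]}_{barcode}_{umi}"


def parse_tagged_name(name: str) -> Tuple[str, str, str]:
    """Invert :func:`tag_read_name`; returns (original, barcode, umi)."""
    parts = name.rsplit("_", 2)
    if len(parts) != 3:
        raise ValueError(f"read name {name!r} lacks the _BARCODE_UMI tag")
    return parts[0], parts[1], parts[2]


def demultiplex(
    r1_path,
    r2_path,
    bs: BarcodeSet,
    rs: ReadStructure,
    outdir,
    max_mismatch: int = 0,
    adapters: Sequence[str] = (),
    polya_min_run: int = 10,
    min_len: int = 20,
    trim: bool = False,
    write_unassigned: bool = True,
    gzip_output: bool = False,
) -> DemuxSummary:
    """Split a pooled R1/R2 pair of FASTQ files into per-sample cDNA FASTQs.

    Each assigned read-2 record is written to ``<outdir>/<sample_id>.fastq``
    with the matched (error-corrected) barcode and observed UMI appended to
    its name. Unassigned reads go to ``unassigned.fastq`` when requested.
    Output files are written atomically; the returned summary satisfies
    ``total == unassigned + sum(per_sample)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_output else ".fastq"
    summary = DemuxSummary()
    sample_barcode = dict(bs.entries)

    import contextlib

    with contextlib.ExitStack() as stack:
        handles: dict[str, IO] = {}
        for sid in bs.sample_ids:
            handles[sid] = stack.enter_context(
                atomic_write(outdir / f"{sid}{ext}", "wt")
            )
        un = (
            stack.enter_context(atomic_write(outdir / f"unassigned{ext}", "wt"))
            if write_unassigned
            else None
        )
        r1 = stack.enter_context(open_maybe_gzip(r1_path, "rt"))
        r2 = stack.enter_context(open_maybe_gzip(r2_path, "rt"))

        for _, (t1, s1, _q1), (t2, s2, q2) in _read_pairs(r1, r2):
            summary.total += 1
            tag = extract_tag(s1, rs)
            if tag is None:
                summary.per_reason[REASON_TOO_SHORT] += 1
                if un is not None:
                    un.write(f"@{t2}\n{s2}\n+\n{q2}\n")
                continue
            observed_bc, umi = tag
            sid, reason = match_barcode(observed_bc, bs, max_mismatch)
            summary.per_reason[reason] += 1
            if sid is UNASSIGNED:
                if un is not None:
                    un.write(f"@{t2}\n{s2}\n+\n{q2}\n")
                continue
            if trim:
                s2, q2, keep = trim_read2(
                    s2, q2, adapters, polya_min_run=polya_min_run, min_len=min_len
                )
                if not keep:
                    # discarded post-assignment reads still count for the sample
                    summary.per_sample[sid] += 1
                    continue
            name = tag_read_name(t2, sample_barcode[sid], umi)
            handles[sid].write(f"@{name}\n{s2}\n+\n{q2}\n")
            summary.per_sample[sid] += 1

    summary.validate()
    return summary
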