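"""Readers and writers for the on-disk formats the tool touches.

Peak dialects
-------------
* MACS narrowPeak: tab-separated BED6+4 (10 columns). The summit is
  ``chromStart + column 10``; an offset of -1 means "not called" and falls
  back to the interval midpoint (floored).
* SEACR BED: 6 columns — chrom, start, end, total signal, max signal, and the
  max-signal region as ``chr:start-end``. SEACR calls no summit, so the
  midpoint of the max-signal region is used as the summit proxy (interval
  midpoint when column 6 is unparseable).

Motifs are accepted as JASPAR PFM text or MEME minimal format (parsed via
Bio.motifs); MEME letter probabilities are converted to counts using the
stated nsites, defaulting to 100 when absent. Reads are BED3+ intervals, with
an optional BAM adapter (pysam) exposing the same contract.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from .errors import BoundsError, FormatError, ValidationError
from .motifs import BASES, PFM
from .peaks import GenomicInterval, Peak

__all__ = [
    "Genome",
    "MotifRecord",
    "read_narrowpeak",
    "read_seacr_bed",
    "read_peaks",
    "read_motifs",
    "read_genome_fasta",
    "read_reads",
    "read_reads_bam",
    "write_peaks_bed",
    "write_motifs_meme",
]

PEAK_DIALECTS = ("macs_narrowpeak", "seacr_bed")


class Genome:
    """Named uppercase DNA sequences with bounds-checked substring access.

    Soft-masked lowercase is uppercased on load; non-ACGT characters are kept
    as N. The underlying storage is mutable so the synthetic generators can
    plant motif instances in place.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs: dict[str, bytearray] = {}
        for name, s in seqs.items():
            up = re.sub(r"[^ACGT]", "N", s.upper())
            self._seqs[name] = bytearray(up.encode())

    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def sequence(self, name: str) -> str:
        return self._seqs[name].decode()

    def fetch(self, name: str, start: int, end: int) -> str:
        if name not in self._seqs:
            raise BoundsError(f"unknown sequence {name!r}")
        n = len(self._seqs[name])
        if start < 0 or end > n or start >= end:
            raise BoundsError(f"[{start},{end}) outside {name} of length {n}")
        return self._seqs[name][start:end].decode()

    def replace(self, name: str, pos: int, segment: str) -> None:
        """Overwrite bases at [pos, pos+len(segment)); used by generators."""
        if pos < 0 or pos + len(segment) > len(self._seqs[name]):
            raise BoundsError(f"replacement at {pos} outside {name}")
        self._seqs[name][pos:pos + len(segment)] = segment.upper().encode()


@dataclass(frozen=True)
class MotifRecord:
    """A named motif: identifier (e.g. a JASPAR matrix ID), display name, PFM."""

    identifier: str
    name: str
    pfm: PFM

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValidationError("motif identifier must be non-empty")


def _split_line(line: str, n_cols: int, path, lineno: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != n_cols:
        raise FormatError(
            f"{path}:{lineno}: expected {n_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def _parse_coords(chrom: str, start_s: str, end_s: str, path, lineno: int) -> tuple[int, int]:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates")
    if start < 0:
        raise ValidationError(f"{path}:{lineno}: negative start {start}")
    if end <= start:
        raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
    return start, end


def read_narrowpeak(path) -> list[Peak]:
    """Parse a MACS narrowPeak (BED6+4) file into peaks, order preserved."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_line(line, 10, path, lineno)
            start, end = _parse_coords(f[0], f[1], f[2], path, lineno)
            try:
                offset = int(f[9])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer summit offset")
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            if not (start <= summit < end):
                raise ValidationError(
                    f"{path}:{lineno}: summit offset {offset} outside peak"
                )
            try:
                score = float(f[4])
            except ValueError:
                score = 0.0
            peaks.append(Peak(chrom=f[0], start=start, end=end, name=f[3],
                              score=score, summit=summit))
    return peaks


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_seacr_bed(path) -> list[Peak]:
    """Parse a SEACR 6-column BED into peaks.

    The summit is the floored midpoint of the column-6 max-signal region
    (interval midpoint when the column does not parse as ``chr:start-end``).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_line(line, 6, path, lineno)
            start, end = _parse_coords(f[0], f[1], f[2], path, lineno)
            m = _REGION_RE.match(f[5])
            if m:
                rs, re_ = int(m.group("start")), int(m.group("end"))
                if re_ < rs:
                    raise ValidationError(
                        f"{path}:{lineno}: inverted max-signal region {f[5]}"
                    )
                summit = (rs + re_) // 2
                if not (start <= summit < end):
                    raise ValidationError(
                        f"{path}:{lineno}: max-signal region outside peak"
                    )
            else:
                summit = start + (end - start) // 2
            try:
                score = float(f[3])
            except ValueError:
                score = 0.0
            peaks.append(Peak(chrom=f[0], start=start, end=end,
                              name=f"{f[0]}:{start}-{end}", score=score,
                              summit=summit))
    return peaks


def read_peaks(path, dialect: str) -> list[Peak]:
    """Dispatch on peak dialect ('macs_narrowpeak' or 'seacr_bed')."""
    if dialect == "macs_narrowpeak":
        return read_narrowpeak(path)
    if dialect == "seacr_bed":
        return read_seacr_bed(path)
    raise ValidationError(f"unknown peak dialect {dialect!r}")


def _counts_from_bio_motif(m) -> np.ndarray:
    cols = len(m.counts["A"])
    counts = np.zeros((4, cols))
    for i, b in enumerate(BASES):
        row = m.counts[b]
        counts[i] = row
    return counts


def read_motifs(path, format: str) -> list[MotifRecord]:
    """Read motifs from JASPAR PFM text or MEME minimal format.

    Counts land in A, C, G, T row order regardless of on-disk order. MEME
    minimal probabilities are scaled to counts by the block's ``nsites``
    (100 when absent).
    """
    text = Path(path).read_text()
    records: list[MotifRecord] = []
    if format == "jaspar_pfm":
        try:
            parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: not valid JASPAR PFM text ({exc})")
        for m in parsed:
            counts = _counts_from_bio_motif(m)
            if (counts < 0).any():
                raise ValidationError(f"{path}: negative counts in {m.matrix_id}")
            ident = m.matrix_id or m.name
            records.append(MotifRecord(ident, m.name or ident, PFM(counts)))
    elif format == "meme_minimal":
        # Bio.motifs assumes nsites=20 when the header omits it; the package
        # convention is 100, so rescale those blocks.
        try:
            parsed = bio_motifs.parse(io.StringIO(text), "minimal")
        except Exception as exc:
            raise FormatError(f"{path}: not valid MEME minimal format ({exc})")
        headers = re.findall(r"letter-probability matrix:[^\n]*", text)
        for m, header in zip(parsed, headers):
            counts = _counts_from_bio_motif(m)
            nsites = m.num_occurrences
            if "nsites=" not in header:
                counts = counts / max(nsites, 1) * 100.0
            if (counts < 0).any():
                raise ValidationError(f"{path}: negative counts in {m.name}")
            records.append(MotifRecord(m.name, m.name, PFM(counts)))
    else:
        raise ValidationError(f"unknown motif format {format!r}")
    if not records:
        raise FormatError(f"{path}: no motifs found")
    return records


def read_genome_fasta(path) -> Genome:
    """Load a FASTA into a Genome (uppercase; non-ACGT kept as N)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return Genome(seqs)


def read_reads(path) -> list[GenomicInterval]:
    """Read aligned fragments from a BED3+ file; an empty file is allowed."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: BED needs >= 3 columns, got {len(fields)}"
                )
            start, end = _parse_coords(fields[0], fields[1], fields[2],
                                       path, lineno)
            reads.append(GenomicInterval(fields[0], start, end))
    return reads


def read_reads_bam(path) -> list[GenomicInterval]:
    """Optional BAM adapter: mapped, non-secondary, non-supplementary records
    as intervals, same contract as :func:`read_reads`."""
    import pysam  # local import keeps the core free of binary-format deps

    reads = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            reads.append(GenomicInterval(rec.reference_name,
                                         rec.reference_start,
                                         rec.reference_end))
    return reads


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """Write peaks as BED6 with the summit encoded as ``name|summit=<pos>``.

    Round-trips through the BED read path: coordinates and summit survive.
    """
    with open(path, "w") as fh:
        for p in peaks:
            base = p.name.split("|summit=")[0]
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t"
                     f"{base}|summit={p.summit}\t{p.score:g}\t.\n")


def read_peaks_bed(path) -> list[Peak]:
    """Read BED6 written by :func:`write_peaks_bed` (summit in name field)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = _split_line(line, 6, path, lineno)
            start, end = _parse_coords(f[0], f[1], f[2], path, lineno)
            name, summit = f[3], -1
            if "|summit=" in name:
                name, _, s = name.rpartition("|summit=")
                summit = int(s)
            try:
                score = float(f[4])
            except ValueError:
                score = 0.0
            peaks.append(Peak(f[0], start, end, name=name, score=score,
                              summit=summit))
    return peaks


def write_motifs_meme(records: Sequence[MotifRecord], path,
                      background=None) -> None:
    """Write motifs in MEME minimal format (re-readable by read_motifs)."""
    bg = background.probs if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(BASES, bg)) + "\n\n")
        for rec in records:
            counts = rec.pfm.counts
            nsites = max(int(round(counts.sum(axis=0).max())), 1)
            freqs = counts / counts.sum(axis=0, keepdims=True)
            fh.write(f"MOTIF {rec.identifier} {rec.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {rec.pfm.width} "
                     f"nsites= {nsites} E= 1\n")
            for j in range(rec.pfm.width):
                fh.write(" ".join(f"{freqs[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")
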