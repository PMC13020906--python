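"""Interval/peak data model, pairwise overlap segregation, width summaries,
and peak sequence extraction.

Coordinates are 0-based half-open (BED convention) throughout. Two intervals
overlap iff ``a.start < b.end and b.start < a.end`` on the same chromosome;
any overlap of >= 1 bp counts. Peaks are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import BoundsError, EmptyInputError, ValidationError

__all__ = [
    "GenomicInterval",
    "Peak",
    "SegregatedPeaks",
    "WidthSummary",
    "segregate_pair",
    "peak_width_summary",
    "extract_peak_sequences",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus a summit (absolute bp, the position of
    maximal fragment pileup or its dialect-specific proxy), a name and a score.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit: int = -1

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValidationError(
                f"invalid peak interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit < 0:
            object.__setattr__(self, "summit", self.start + self.width // 2)
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} outside peak "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class SegregatedPeaks:
    """The four overlap groups of one pairwise comparison.

    ``common_ref``/``unique_ref`` partition the reference peaks according to
    whether each overlaps at least one comparison peak; ``common_cmp``/
    ``unique_cmp`` partition the comparison peaks symmetrically. Both sides of
    the common set are kept separately (they are different peak calls over the
    same loci).
    """

    common_ref: list[Peak]
    unique_ref: list[Peak]
    common_cmp: list[Peak]
    unique_cmp: list[Peak]
    ref_label: str = "ref"
    cmp_label: str = "cmp"

    GROUPS = ("common_ref", "common_cmp", "unique_ref", "unique_cmp")

    def group(self, label: str) -> list[Peak]:
        if label not in self.GROUPS:
            raise KeyError(label)
        return getattr(self, label)


@dataclass
class WidthSummary:
    mean: float
    median: float
    widths: np.ndarray = field(repr=False)


def _merged_intervals(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays, sorted by start."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s < merged[-1][1]:  # touching intervals stay separate
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def overlaps_any(queries: Sequence[Peak | GenomicInterval],
                 targets: Sequence[Peak | GenomicInterval]) -> np.ndarray:
    """Boolean mask: does each query overlap >= 1 bp of any target?

    Uses searchsorted against the merged target union per chromosome, which is
    equivalent to any-overlap against the unmerged set.
    """
    merged = _merged_intervals(list(targets))  # type: ignore[arg-type]
    mask = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        got = merged.get(q.chrom)
        if got is None:
            continue
        starts, ends = got
        # first merged interval ending strictly after q.start
        j = int(np.searchsorted(ends, q.start, side="right"))
        mask[i] = j < len(starts) and starts[j] < q.end
    return mask


def segregate_pair(ref: Sequence[Peak], cmp: Sequence[Peak],
                   ref_label: str = "ref", cmp_label: str = "cmp") -> SegregatedPeaks:
    """Split two peak sets into common/unique groups by any-overlap.

    A reference peak is *common* iff it overlaps at least one comparison peak
    by >= 1 bp on the same chromosome; symmetrically for comparison peaks.
    Every input peak lands in exactly one group; input order is preserved.
    Empty inputs are allowed.
    """
    ref = list(ref)
    cmp = list(cmp)
    ref_common = overlaps_any(ref, cmp) if ref and cmp else np.zeros(len(ref), bool)
    cmp_common = overlaps_any(cmp, ref) if ref and cmp else np.zeros(len(cmp), bool)
    return SegregatedPeaks(
        common_ref=[p for p, c in zip(ref, ref_common) if c],
        unique_ref=[p for p, c in zip(ref, ref_common) if not c],
        common_cmp=[p for p, c in zip(cmp, cmp_common) if c],
        unique_cmp=[p for p, c in zip(cmp, cmp_common) if not c],
        ref_label=ref_label,
        cmp_label=cmp_label,
    )


def peak_width_summary(peaks: Sequence[Peak]) -> WidthSummary:
    """Mean and median of peak widths (end - start).

    The median of an even count is the average of the central pair.
    """
    if not peaks:
        raise EmptyInputError("peak_width_summary requires a non-empty peak set")
    widths = np.asarray([p.width for p in peaks], dtype=np.int64)
    return WidthSummary(mean=float(widths.mean()),
                        median=float(np.median(widths)),
                        widths=widths)


def extract_peak_sequences(peaks: Iterable[Peak], genome) -> list[tuple[str, str]]:
    """Extract the uppercase sequence of each peak's [start, end).

    Returns (peak id, sequence) pairs in input order; the id is the peak name
    when informative, else ``chrom:start-end``. Raises BoundsError naming the
    offending peak if it exceeds its chromosome.
    """
    out = []
    for p in peaks:
        try:
            seq = genome.fetch(p.chrom, p.start, p.end)
        except BoundsError as exc:
            raise BoundsError(f"peak {p.name} ({p.chrom}:{p.start}-{p.end}): {exc}")
        pid = p.name if p.name not in (".", "") else f"{p.chrom}:{p.start}-{p.end}"
        out.append((pid, seq))
    return out
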