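"""Motif-motif comparison by offset-aligned Pearson correlation.

Two motifs are compared by sliding one over the other (ungapped, both
strands when allowed), computing at every offset with at least ``min_overlap``
aligned columns the Pearson correlation of the two flattened 4 x overlap
frequency submatrices, and keeping the maximum. Ties prefer the smaller
|offset|, then the + strand. Ranking uses the raw correlation; no p-value
machinery.

The four comparison heatmaps of a pairwise benchmark follow a fixed
orientation: motifs discovered in common-reference (mA), common-comparison
(mB), unique-reference (mC) and unique-comparison (mD) peaks combine as
common = mA x mB, unique = mC x mD, cross A = mC x mB, cross B = mD x mA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats import MotifRecord
from .motifs import PFM, reverse_complement

__all__ = [
    "MotifAlignment",
    "ComparisonHeatmaps",
    "KnownMatch",
    "motif_pcc",
    "similarity_matrix",
    "build_comparison_heatmaps",
    "nearest_known",
]

DEFAULT_MIN_OVERLAP = 4
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class MotifAlignment:
    pcc: float
    offset: int      # columns of b's start relative to a's start
    strand: str      # '+' or '-' (b reverse-complemented)
    overlap: int     # aligned columns


@dataclass
class ComparisonHeatmaps:
    """Best-PCC matrices for the four group-motif comparisons (labelled
    DataFrames; axes carry mA/mB/mC/mD-prefixed identifiers)."""

    common: pd.DataFrame    # mA x mB
    unique: pd.DataFrame    # mC x mD
    cross_a: pd.DataFrame   # mC x mB
    cross_b: pd.DataFrame   # mD x mA


@dataclass(frozen=True)
class KnownMatch:
    query_id: str
    database_id: str
    database_name: str
    alignment: MotifAlignment


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:  # a constant block carries no shape information
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def motif_pcc(a: PFM, b: PFM, min_overlap: int = DEFAULT_MIN_OVERLAP,
              allow_rc: bool = True) -> MotifAlignment:
    """Best offset-aligned Pearson correlation between two motifs.

    Both PFMs are column-normalized to frequencies first; the correlation at
    an offset uses only the overlapping columns.
    """
    if min_overlap < 4:
        raise ValidationError("min_overlap must be >= 4")
    wa, wb = a.width, b.width
    if wa < min_overlap or wb < min_overlap:
        raise ValidationError(
            f"motif widths ({wa}, {wb}) below min_overlap {min_overlap}"
        )
    fa = a.frequencies()
    candidates = [("+", b.frequencies())]
    if allow_rc:
        candidates.append(("-", reverse_complement(b).frequencies()))
    best: MotifAlignment | None = None
    for strand, fb in candidates:
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(wa, offset + wb)
            if a_hi - a_lo < min_overlap:
                continue
            b_lo = a_lo - offset
            sub_a = fa[:, a_lo:a_hi].ravel()
            sub_b = fb[:, b_lo:b_lo + (a_hi - a_lo)].ravel()
            pcc = _pearson(sub_a, sub_b)
            cand = MotifAlignment(pcc=pcc, offset=offset, strand=strand,
                                  overlap=a_hi - a_lo)
            if best is None or _better(cand, best):
                best = cand
    assert best is not None
    return best


def _better(cand: MotifAlignment, best: MotifAlignment) -> bool:
    if cand.pcc > best.pcc + _TIE_EPS:
        return True
    if cand.pcc < best.pcc - _TIE_EPS:
        return False
    if abs(cand.offset) != abs(best.offset):
        return abs(cand.offset) < abs(best.offset)
    return cand.strand == "+" and best.strand == "-"


def similarity_matrix(list_a: Sequence[PFM], list_b: Sequence[PFM],
                      labels_a: Sequence[str] | None = None,
                      labels_b: Sequence[str] | None = None,
                      min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Matrix of best PCC values, rows = list_a, columns = list_b.

    Empty lists yield an empty, correctly-labelled matrix.
    """
    labels_a = list(labels_a) if labels_a is not None else \
        [f"m{i + 1}" for i in range(len(list_a))]
    labels_b = list(labels_b) if labels_b is not None else \
        [f"m{j + 1}" for j in range(len(list_b))]
    values = np.zeros((len(list_a), len(list_b)))
    for i, ma in enumerate(list_a):
        for j, mb in enumerate(list_b):
            values[i, j] = motif_pcc(ma, mb, min_overlap=min_overlap).pcc
    return pd.DataFrame(values, index=labels_a, columns=labels_b)


def _group_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def build_comparison_heatmaps(common_ref: Sequence[PFM],
                              common_cmp: Sequence[PFM],
                              unique_ref: Sequence[PFM],
                              unique_cmp: Sequence[PFM],
                              min_overlap: int = DEFAULT_MIN_OVERLAP
                              ) -> ComparisonHeatmaps:
    """The four heatmaps of one pairwise comparison.

    cross A compares unique-reference motifs (mC) to common-comparison motifs
    (mB); cross B compares unique-comparison motifs (mD) to common-reference
    motifs (mA). High cross-B values flag signal the reference captures in
    its common peaks that the comparison only finds in peaks of its own.
    """
    mA = _group_labels("mA", len(common_ref))
    mB = _group_labels("mB", len(common_cmp))
    mC = _group_labels("mC", len(unique_ref))
    mD = _group_labels("mD", len(unique_cmp))
    return ComparisonHeatmaps(
        common=similarity_matrix(common_ref, common_cmp, mA, mB, min_overlap),
        unique=similarity_matrix(unique_ref, unique_cmp, mC, mD, min_overlap),
        cross_a=similarity_matrix(unique_ref, common_cmp, mC, mB, min_overlap),
        cross_b=similarity_matrix(unique_cmp, common_ref, mD, mA, min_overlap),
    )


def nearest_known(query: PFM, database: Sequence[MotifRecord],
                  query_id: str = "query",
                  min_overlap: int = DEFAULT_MIN_OVERLAP) -> KnownMatch | None:
    """Closest database motif to the query by best-alignment PCC.

    Ties go to the earlier database entry. Returns None when no database
    entry satisfies the overlap requirement.
    """
    if not database:
        raise ValidationError("nearest_known requires a non-empty database")
    best: KnownMatch | None = None
    for rec in database:
        if query.width < min_overlap or rec.pfm.width < min_overlap:
            continue
        aln = motif_pcc(query, rec.pfm, min_overlap=min_overlap)
        if best is None or aln.pcc > best.alignment.pcc + _TIE_EPS:
            best = KnownMatch(query_id=query_id, database_id=rec.identifier,
                              database_name=rec.name, alignment=aln)
    return best
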