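"""Known-motif enrichment per segregated peak group, and FRiP.

A peak is "enriched" for a motif when its sequence contains at least one
significant occurrence on either strand (zero-or-one-occurrence-per-sequence
presence). Group-level results are counts and percentages of enriched peaks;
the unique-versus-common contrast within each experiment side is quantified
with a two-sided Fisher exact test.

FRiP (fraction of reads in peaks) counts a read as in-peak when it overlaps
any peak by >= 1 bp; each read counts at most once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError
from .formats import Genome, MotifRecord
from .motifs import BackgroundModel, pfm_to_pwm
from .peaks import GenomicInterval, Peak, SegregatedPeaks, extract_peak_sequences, overlaps_any
from .scanning import (DEFAULT_P_THRESHOLD, null_score_distribution,
                       scan_sequences)

__all__ = [
    "GroupEnrichment",
    "FripResult",
    "peak_has_motif",
    "group_enrichment",
    "enrichment_contrast",
    "frip",
    "enrichment_table",
]


@dataclass(frozen=True)
class GroupEnrichment:
    group: str               # one of SegregatedPeaks.GROUPS
    motif_id: str
    n_peaks: int
    n_enriched: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_enriched / self.n_peaks if self.n_peaks else 0.0


@dataclass(frozen=True)
class FripResult:
    n_reads: int
    n_in_peaks: int

    @property
    def frip(self) -> float:
        return self.n_in_peaks / self.n_reads


def peak_has_motif(peak_seq: str, pwm, p_threshold: float = DEFAULT_P_THRESHOLD,
                   null=None) -> bool:
    """True iff the sequence has >= 1 occurrence at p <= threshold, either strand."""
    return bool(scan_sequences(pwm, [("q", peak_seq)], p_threshold, null=null))


def group_enrichment(seg: SegregatedPeaks, motif_records: Sequence[MotifRecord],
                     genome: Genome,
                     p_threshold: float = DEFAULT_P_THRESHOLD) -> list[GroupEnrichment]:
    """Per-(group, motif) enriched-peak counts across the four overlap groups.

    The scanning background is the 0-order composition of all peak sequences
    in the comparison (strand-symmetrized), falling back to uniform when no
    sequence is available. Empty groups yield (0, 0).
    """
    group_seqs = {g: extract_peak_sequences(seg.group(g), genome)
                  for g in SegregatedPeaks.GROUPS}
    all_seqs = [s for seqs in group_seqs.values() for _, s in seqs]
    background = BackgroundModel.from_sequences(all_seqs) if all_seqs else \
        BackgroundModel.uniform()
    results = []
    for rec in motif_records:
        pwm = pfm_to_pwm(rec.pfm, background)
        null = null_score_distribution(pwm)
        for g in SegregatedPeaks.GROUPS:
            seqs = group_seqs[g]
            n_hit = sum(peak_has_motif(s, pwm, p_threshold, null=null)
                        for _, s in seqs)
            results.append(GroupEnrichment(group=g, motif_id=rec.identifier,
                                           n_peaks=len(seqs), n_enriched=n_hit))
    return results


def enrichment_contrast(a: GroupEnrichment, b: GroupEnrichment) -> float:
    """Two-sided Fisher exact p-value contrasting two groups' enrichment.

    Table: [[a.n_enriched, a.n_peaks - a.n_enriched],
            [b.n_enriched, b.n_peaks - b.n_enriched]].
    A table with a zero margin gives p = 1 by convention.
    """
    table = np.array([[a.n_enriched, a.n_peaks - a.n_enriched],
                      [b.n_enriched, b.n_peaks - b.n_enriched]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def enrichment_table(results: Sequence[GroupEnrichment]) -> pd.DataFrame:
    """Tidy per-(group, motif) table with unique-vs-common Fisher contrasts."""
    rows = []
    by_key = {(r.motif_id, r.group): r for r in results}
    for r in results:
        contrast = np.nan
        side = r.group.rsplit("_", 1)[1]
        other = by_key.get((r.motif_id,
                            ("unique_" if r.group.startswith("common") else "common_") + side))
        if other is not None and r.n_peaks and other.n_peaks:
            contrast = enrichment_contrast(r, other)
        rows.append({"group": r.group, "motif": r.motif_id,
                     "n_peaks": r.n_peaks, "n_enriched": r.n_enriched,
                     "percentage": r.percentage,
                     "fisher_p_vs_counterpart": contrast})
    return pd.DataFrame(rows)


def frip(reads: Sequence[GenomicInterval], peaks: Sequence[Peak]) -> FripResult:
    """Fraction of reads overlapping (>= 1 bp) any peak."""
    reads = list(reads)
    if not reads:
        raise EmptyInputError("frip requires at least one read")
    if not peaks:
        return FripResult(n_reads=len(reads), n_in_peaks=0)
    mask = overlaps_any(reads, peaks)
    return FripResult(n_reads=len(reads), n_in_peaks=int(mask.sum()))
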