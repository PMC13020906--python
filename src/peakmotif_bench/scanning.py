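"""PWM occurrence calling with exact null-score p-values.

Scoring discretizes the log-odds matrix to integer units (default 1000 units
per bit) and computes the exact probability mass function of the score of a
random w-mer drawn i.i.d. from the background, by position-wise convolution.
A window's p-value is the null tail mass at its (integer) score. Both strands
are scored against the same null distribution, so scanning the reverse
complement of a sequence yields the strand-swapped, coordinate-mirrored
occurrence set exactly; with the default strand-symmetrized background the
shared null is also the exact null for the minus strand.

Windows containing N are skipped. Occurrence center is start + floor(w/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyInputError
from .motifs import BASES, PWM
from .peaks import Peak

__all__ = [
    "DEFAULT_SCALE",
    "DEFAULT_P_THRESHOLD",
    "ScoreDistribution",
    "MotifOccurrence",
    "DistanceSummary",
    "null_score_distribution",
    "scan_sequences",
    "summit_to_motif",
    "bootstrap_distances",
    "encode_sequence",
]

DEFAULT_SCALE = 1000
DEFAULT_P_THRESHOLD = 1e-4

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 array with A=0, C=1, G=2, T=3, other=-1."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class ScoreDistribution:
    """Exact PMF of the integer-scaled PWM score under the background."""

    support: np.ndarray      # ascending integer scores (offset + index)
    pmf: np.ndarray          # probabilities, sum 1
    scale: int               # integer units per bit

    def __post_init__(self) -> None:
        # survival[i] = P(score >= support[i]); monotone non-increasing
        self._sf = np.cumsum(self.pmf[::-1])[::-1]

    def pvalue(self, int_score: int | np.ndarray) -> np.ndarray:
        """Tail mass P(S >= s) for integer score(s) s."""
        idx = np.searchsorted(self.support, np.asarray(int_score), side="left")
        sf = np.append(self._sf, 0.0)
        return sf[np.minimum(idx, len(self.support))]

    def min_score_for_p(self, p_threshold: float) -> int:
        """Smallest integer score whose tail mass is <= p_threshold."""
        ok = self._sf <= p_threshold
        if not ok.any():
            return int(self.support[-1]) + 1  # unreachable: nothing passes
        return int(self.support[int(np.argmax(ok))])


@dataclass(frozen=True)
class MotifOccurrence:
    seq_id: str
    start: int          # 0-based within the scanned sequence
    strand: str         # '+' or '-'
    score: float        # bits
    pvalue: float
    width: int

    @property
    def center(self) -> int:
        return self.start + self.width // 2


@dataclass
class DistanceSummary:
    """Signed summit-to-motif distances for peaks with >= 1 occurrence."""

    distances: np.ndarray            # summit - nearest occurrence center, bp
    n_peaks: int                     # peaks considered
    n_without_occurrence: int        # peaks excluded (no occurrence)
    mean_absolute: float
    bootstrap_ci: tuple[float, float] | None = None


def integer_matrix(pwm: PWM, scale: int = DEFAULT_SCALE) -> np.ndarray:
    """Round the log-odds matrix to integer units of 1/scale bits."""
    return np.rint(pwm.logodds * scale).astype(np.int64)


def null_score_distribution(pwm: PWM, background=None,
                            scale: int = DEFAULT_SCALE) -> ScoreDistribution:
    """Exact null PMF of the integer-scaled score of a background w-mer.

    Position-wise convolution over the dense integer score range; exact up to
    the rounding induced by ``scale``.
    """
    bg = (background or pwm.background).probs
    ints = integer_matrix(pwm, scale)
    lo = int(ints.min(axis=0).sum())
    hi = int(ints.max(axis=0).sum())
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(ints.shape[1]):
        col = ints[:, j]
        new_lo = cur_lo + int(col.min())
        new = np.zeros(len(cur) + int(col.max() - col.min()))
        for b in range(4):
            off = int(col[b]) - int(col.min())
            new[off:off + len(cur)] += cur * bg[b]
        cur, cur_lo = new, new_lo
    assert cur_lo == lo and cur_lo + len(cur) - 1 == hi
    support = np.arange(lo, hi + 1, dtype=np.int64)
    nonzero = cur > 0
    return ScoreDistribution(support=support[nonzero], pmf=cur[nonzero],
                             scale=scale)


def _window_scores(codes: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every window and a validity mask (no N)."""
    w = ints.shape[1]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    scores = np.zeros(n_win, dtype=np.int64)
    for j in range(w):
        scores += ints[safe[j:j + n_win], j]
    bad = (codes < 0).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[w:] - cbad[:-w]) == 0
    return scores, valid


def scan_sequences(pwm: PWM, seqs: Sequence[tuple[str, str]],
                   p_threshold: float = DEFAULT_P_THRESHOLD,
                   scale: int = DEFAULT_SCALE,
                   null: ScoreDistribution | None = None) -> list[MotifOccurrence]:
    """Report every window on both strands with null p-value <= threshold.

    ``seqs`` is a collection of (id, DNA) pairs. Sequences shorter than the
    motif yield no occurrences. Output is sorted by (id, start, strand).
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    if null is None:
        null = null_score_distribution(pwm, scale=scale)
    ints_fwd = integer_matrix(pwm, scale)
    ints_rev = ints_fwd[::-1, ::-1]
    min_int = null.min_score_for_p(p_threshold)
    w = pwm.width
    occs: list[MotifOccurrence] = []
    for seq_id, seq in seqs:
        codes = encode_sequence(seq)
        for strand, ints in (("+", ints_fwd), ("-", ints_rev)):
            scores, valid = _window_scores(codes, ints)
            hits = np.nonzero(valid & (scores >= min_int))[0]
            if len(hits) == 0:
                continue
            pvals = null.pvalue(scores[hits])
            for pos, s, p in zip(hits, scores[hits], pvals):
                occs.append(MotifOccurrence(seq_id=seq_id, start=int(pos),
                                            strand=strand,
                                            score=float(s) / scale,
                                            pvalue=float(p), width=w))
    occs.sort(key=lambda o: (o.seq_id, o.start, o.strand))
    return occs


def summit_to_motif(peaks: Sequence[Peak], pwm: PWM, genome,
                    p_threshold: float = DEFAULT_P_THRESHOLD,
                    scale: int = DEFAULT_SCALE,
                    null: ScoreDistribution | None = None,
                    n_boot: int = 0, seed: int = 0) -> DistanceSummary:
    """Signed distance from each peak summit to its nearest motif occurrence.

    Only occurrences inside the peak count. Distance = summit - occurrence
    center; among several occurrences the one with the smallest |distance| is
    chosen, ties going to the leftmost. Peaks with no occurrence are excluded
    from the statistics and counted separately. With ``n_boot`` > 0 a
    percentile bootstrap CI of the mean absolute distance is attached.
    """
    from .peaks import extract_peak_sequences

    if null is None:
        null = null_score_distribution(pwm, scale=scale)
    named = extract_peak_sequences(peaks, genome)
    distances = []
    n_missing = 0
    for peak, (pid, seq) in zip(peaks, named):
        occs = scan_sequences(pwm, [(pid, seq)], p_threshold, scale, null)
        if not occs:
            n_missing += 1
            continue
        # occs sorted by start, so min() tie-breaks toward the leftmost
        best = min(occs, key=lambda o: abs(peak.summit - (peak.start + o.center)))
        distances.append(peak.summit - (peak.start + best.center))
    dist = np.asarray(distances, dtype=np.int64)
    mean_abs = float(np.abs(dist).mean()) if len(dist) else float("nan")
    ci = None
    if n_boot > 0 and len(dist) > 0:
        ci = bootstrap_distances(dist, n_boot=n_boot, seed=seed)
    return DistanceSummary(distances=dist, n_peaks=len(peaks),
                           n_without_occurrence=n_missing,
                           mean_absolute=mean_abs, bootstrap_ci=ci)


def bootstrap_distances(distances: Sequence[int], n_boot: int = 2000,
                        seed: int = 0) -> tuple[float, float]:
    """Percentile (2.5, 97.5) bootstrap CI of the mean absolute distance.

    Resamples with replacement at the original n, ``n_boot`` times;
    deterministic given ``seed``.
    """
    dist = np.abs(np.asarray(distances, dtype=float))
    if len(dist) == 0:
        raise EmptyInputError("bootstrap_distances needs a non-empty vector")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(dist), size=(n_boot, len(dist)))
    means = dist[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)
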