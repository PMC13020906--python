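"""De-novo motif discovery on peak sequences.

The discoverer is a k-mer-seeded ZOOPS (zero-or-one occurrence per sequence)
pipeline: a dinucleotide-preserving shuffle of the input provides the control
set; candidate seeds are the k-mers (merged with their reverse complements)
most enriched in the input versus the control by a one-sided Fisher exact
test on per-sequence presence; the best seed is expanded with flanking
columns and refined by a fixed number of ZOOPS site-realignment iterations;
accepted motifs have their sites masked before the next round so each round
finds something new. A low-complexity filter discards motifs whose consensus
contains a run of ``filter_n`` identical letters.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateMotifError, InsufficientDataError
from .motifs import BASES, PFM, BackgroundModel, consensus, pfm_to_pwm, revcomp_seq
from .scanning import encode_sequence, integer_matrix, null_score_distribution
from .scanning import _window_scores

__all__ = [
    "DiscoveredMotif",
    "shuffle_control",
    "seed_kmers",
    "refine_motif",
    "repeat_filter",
    "discover_motifs",
]

DEFAULT_K_RANGE = (6, 7, 8, 9, 10)
DEFAULT_FLANK = 2
DEFAULT_ITERS = 3
SEED_P_CUTOFF = 0.05


@dataclass
class DiscoveredMotif:
    pfm: PFM
    seed_kmer: str
    enrichment_pvalue: float
    rank: int
    group: str = ""

    @property
    def consensus(self) -> str:
        return consensus(self.pfm)


def _dinuc_shuffle_one(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson dinucleotide-preserving shuffle of one sequence.

    Preserves the per-sequence mono- and dinucleotide count multisets exactly
    (an Euler-path shuffle of the adjacency multigraph).
    """
    s = seq.upper()
    if len(s) < 2:
        return s
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    first, last = s[0], s[-1]
    vertices = set(edges) | {last}
    if len(vertices) == 1:
        return s
    # choose a random "last out-edge" per non-terminal vertex such that
    # following last edges from every vertex reaches the terminal vertex
    non_terminal = [v for v in vertices if v != last and edges[v]]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))]
                     for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    remaining: dict[str, list[str]] = {}
    for v in vertices:
        lst = list(edges[v])
        if v in last_edge:
            lst.remove(last_edge[v])
        rng.shuffle(lst)
        if v in last_edge:
            lst.append(last_edge[v])
        remaining[v] = lst
    out = [first]
    cur = first
    nxt_idx = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        lst = remaining[cur]
        cur = lst[nxt_idx[cur]]
        nxt_idx[out[-1]] += 1
        out.append(cur)
    return "".join(out)


def shuffle_control(seqs: Sequence[str], seed: int = 0) -> list[str]:
    """Per-sequence dinucleotide-preserving shuffles; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return [_dinuc_shuffle_one(s, rng) for s in seqs]


def _canonical(kmer: str) -> str:
    rc = revcomp_seq(kmer)
    return kmer if kmer <= rc else rc


def _presence_counts(seqs: Sequence[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        su = s.upper()
        seen = set()
        for i in range(len(su) - k + 1):
            kmer = su[i:i + k]
            if "N" in kmer:
                continue
            seen.add(_canonical(kmer))
        counts.update(seen)
    return counts


def seed_kmers(pos: Sequence[str], ctrl: Sequence[str], k: int,
               top: int = 5) -> list[tuple[str, float]]:
    """Rank canonical k-mers by ZOOPS enrichment in pos versus ctrl.

    Presence counts are per-sequence (a k-mer or its reverse complement
    occurring at least once). Ranking is by one-sided Fisher exact p-value
    (enrichment direction); k-mers no more frequent in pos than in ctrl get
    p = 1. Ties break lexicographically on the canonical k-mer.
    """
    if not (4 <= k <= 12):
        raise ValueError("k must be in [4, 12]")
    if top < 1:
        raise ValueError("top must be >= 1")
    n_pos, n_ctrl = len(pos), len(ctrl)
    pos_counts = _presence_counts(pos, k)
    ctrl_counts = _presence_counts(ctrl, k)
    if not pos_counts:
        return []
    kmers = sorted(pos_counts)
    a = np.array([pos_counts[x] for x in kmers])
    b = np.array([ctrl_counts.get(x, 0) for x in kmers])
    # one-sided Fisher (greater) == hypergeometric tail with fixed margins
    pvals = stats.hypergeom.sf(a - 1, n_pos + n_ctrl, a + b, n_pos)
    no_enrich = a * n_ctrl <= b * n_pos
    pvals = np.where(no_enrich, 1.0, pvals)
    order = sorted(range(len(kmers)), key=lambda i: (pvals[i], kmers[i]))
    return [(kmers[i], float(pvals[i])) for i in order[:top]]


def _exact_site_windows(seed: str, seqs: Sequence[str], flank: int
                        ) -> tuple[list[str], list[tuple[int, int, int]]]:
    """All seed / reverse-complement match windows with flanks, plus their
    (sequence index, start, width) placements."""
    k = len(seed)
    w = k + 2 * flank
    rc = revcomp_seq(seed)
    sites, places = [], []
    for si, s in enumerate(seqs):
        su = s.upper()
        for i in range(len(su) - k + 1):
            kmer = su[i:i + k]
            if kmer != seed and kmer != rc:
                continue
            lo = i - flank
            if lo < 0 or lo + w > len(su):
                continue
            window = su[lo:lo + w]
            sites.append(window if kmer == seed else revcomp_seq(window))
            places.append((si, lo, w))
    return sites, places


def _refine(seed: str, pos: Sequence[str], flank: int, iters: int
            ) -> tuple[PFM, list[tuple[int, int, int]]]:
    sites, places = _exact_site_windows(seed, pos, flank)
    if not sites:
        raise DegenerateMotifError(f"seed {seed!r} absent from all sequences")
    pfm = PFM.from_sites(sites)
    background = BackgroundModel.from_sequences(pos)
    codes = [encode_sequence(s) for s in pos]
    for _ in range(iters):
        pwm = pfm_to_pwm(pfm, background)
        null = null_score_distribution(pwm)
        cdf = np.cumsum(null.pmf)
        median_int = int(null.support[int(np.searchsorted(cdf, 0.5))])
        ints_fwd = integer_matrix(pwm)
        ints_rev = ints_fwd[::-1, ::-1]
        new_sites, new_places = [], []
        for si, (s, c) in enumerate(zip(pos, codes)):
            best = None  # (score, start, strand)
            for strand, ints in (("+", ints_fwd), ("-", ints_rev)):
                scores, valid = _window_scores(c, ints)
                if not valid.any():
                    continue
                masked = np.where(valid, scores, np.iinfo(np.int64).min)
                i = int(masked.argmax())
                if valid[i] and (best is None or masked[i] > best[0]):
                    best = (int(masked[i]), i, strand)
            if best is None or best[0] <= median_int:
                continue
            w = pwm.width
            window = s.upper()[best[1]:best[1] + w]
            new_sites.append(window if best[2] == "+" else revcomp_seq(window))
            new_places.append((si, best[1], w))
        if len(new_sites) < 2:
            break
        pfm = PFM.from_sites(new_sites)
        places = new_places
    return pfm, places


def refine_motif(seed: str, pos: Sequence[str], flank: int = DEFAULT_FLANK,
                 iters: int = DEFAULT_ITERS) -> PFM:
    """Expand a seed k-mer into a PFM by ZOOPS site realignment.

    Initializes from all exact seed (or reverse complement) matches with
    ``flank`` extra columns each side, then repeats a fixed number of times:
    take each sequence's best-scoring window above the null median score and
    rebuild the PFM from those aligned sites. Deterministic.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    pfm, _ = _refine(seed, pos, flank, iters)
    return pfm


def repeat_filter(pfm: PFM, filter_n: int) -> bool:
    """True (= discard) iff the consensus has >= filter_n identical letters
    in a row."""
    if filter_n < 2:
        raise ValueError("filter_n must be >= 2")
    cons = consensus(pfm)
    run, prev = 1, ""
    for ch in cons:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run >= filter_n:
            return True
    return False


def discover_motifs(seqs: Sequence[str], count: int = 3, filter_n: int = 6,
                    seed: int = 0, k_range: Sequence[int] = DEFAULT_K_RANGE,
                    flank: int = DEFAULT_FLANK, iters: int = DEFAULT_ITERS
                    ) -> list[DiscoveredMotif]:
    """Discover up to ``count`` motifs, most enriched seed first.

    Each round shuffles the current (masked) sequences into a fresh control,
    sweeps k over ``k_range`` for the best seed, refines it, applies the
    consecutive-repeat filter, and masks the motif's sites with N so the next
    round cannot rediscover it. Rounds stop early when no seed clears the
    enrichment cutoff.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if len(seqs) < 5:
        raise InsufficientDataError(
            f"motif discovery needs >= 5 sequences, got {len(seqs)}"
        )
    working = [s.upper() for s in seqs]
    results: list[DiscoveredMotif] = []
    max_attempts = count + 5
    for attempt in range(max_attempts):
        if len(results) >= count:
            break
        ctrl = shuffle_control(working, seed=seed + attempt)
        best: tuple[float, str] | None = None
        for k in k_range:
            ranked = seed_kmers(working, ctrl, k, top=1)
            if ranked and (best is None or (ranked[0][1], ranked[0][0]) < best):
                best = (ranked[0][1], ranked[0][0])
        if best is None or best[0] >= SEED_P_CUTOFF:
            break
        pval, kmer = best
        try:
            pfm, places = _refine(kmer, working, flank, iters)
        except DegenerateMotifError:
            # seed matches exist only at sequence edges; mask them and move on
            _, edge_places = _exact_site_windows(kmer, working, 0)
            for si, start, w in edge_places:
                working[si] = (working[si][:start] + "N" * w
                               + working[si][start + w:])
            continue
        # mask used sites (and any residual exact seed matches) before the
        # next round, whether or not the motif survives the filter
        _, seed_places = _exact_site_windows(kmer, working, 0)
        for si, start, w in places + seed_places:
            working[si] = working[si][:start] + "N" * w + working[si][start + w:]
        if repeat_filter(pfm, filter_n):
            continue
        results.append(DiscoveredMotif(pfm=pfm, seed_kmer=kmer,
                                       enrichment_pvalue=pval,
                                       rank=len(results) + 1))
    return results
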