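"""Position frequency matrices (PFM), background models, and log-odds PWMs.

Row order is always A, C, G, T; log-odds are base 2 (bits). The pseudocount
is distributed proportionally to the background composition, so a PWM cell is

    log2( (n_bj + c * bg_b) / (N_j + c) / bg_b )

with n_bj the count of base b in column j, N_j the column sum, c the
pseudocount and bg_b the background probability of b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateMotifError, ValidationError

__all__ = [
    "BASES",
    "PFM",
    "BackgroundModel",
    "PWM",
    "pfm_to_pwm",
    "reverse_complement",
    "information_content",
    "consensus",
    "revcomp_seq",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp_seq(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PFM:
    """A 4 x w matrix of non-negative base counts (rows A, C, G, T)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValidationError(f"PFM must be 4 x w, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValidationError("PFM counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValidationError("every PFM column must have positive total count")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def frequencies(self, pseudocount: float = 0.0,
                    background: "BackgroundModel | None" = None) -> np.ndarray:
        """Column-normalized frequencies, optionally pseudocounted."""
        bg = (background or BackgroundModel.uniform()).probs
        num = self.counts + pseudocount * bg[:, None]
        return num / num.sum(axis=0, keepdims=True)

    @classmethod
    def from_sites(cls, sites: Iterable[str]) -> "PFM":
        """Build a PFM by stacking aligned equal-length sites (N ignored)."""
        sites = list(sites)
        w = len(sites[0])
        counts = np.zeros((4, w))
        for s in sites:
            if len(s) != w:
                raise ValidationError("sites must share one length")
            for j, ch in enumerate(s.upper()):
                i = _BASE_INDEX.get(ch)
                if i is not None:
                    counts[i, j] += 1
        return cls(counts)


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order background base probabilities (A, C, G, T)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4,) or (probs <= 0).any():
            raise ValidationError("background needs 4 strictly positive probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("background probabilities must sum to 1")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], symmetrize: bool = True) -> "BackgroundModel":
        """Estimate 0-order frequencies from sequences (non-ACGT ignored).

        With ``symmetrize`` the A/T and C/G probabilities are averaged, which
        makes forward and reverse-strand scanning share one null model.
        Falls back to uniform when no ACGT bases are present.
        """
        counts = np.zeros(4)
        for s in seqs:
            su = s.upper()
            for i, b in enumerate(BASES):
                counts[i] += su.count(b)
        if counts.sum() == 0:
            return cls.uniform()
        if symmetrize:
            at = (counts[0] + counts[3]) / 2
            cg = (counts[1] + counts[2]) / 2
            counts = np.array([at, cg, cg, at])
        counts = np.maximum(counts, 1e-6)
        return cls(counts / counts.sum())


@dataclass(frozen=True)
class PWM:
    """Log-odds (bits) transform of a PFM against a background model."""

    logodds: np.ndarray
    source_pfm: PFM
    background: BackgroundModel
    pseudocount: float

    @property
    def width(self) -> int:
        return self.logodds.shape[1]

    def reverse_complement_logodds(self) -> np.ndarray:
        """Log-odds matrix matching the motif on the opposite strand."""
        return self.logodds[::-1, ::-1]


def pfm_to_pwm(pfm: PFM, background: BackgroundModel | None = None,
               pseudocount: float = 0.1) -> PWM:
    """Log-odds transform; pseudocount split proportionally to background."""
    bg = background or BackgroundModel.uniform()
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (pfm.counts == 0).any():
        raise DegenerateMotifError(
            "PFM has zero cells; a positive pseudocount is required"
        )
    colsum = pfm.counts.sum(axis=0, keepdims=True)
    p_hat = (pfm.counts + pseudocount * bg.probs[:, None]) / (colsum + pseudocount)
    logodds = np.log2(p_hat / bg.probs[:, None])
    return PWM(logodds=logodds, source_pfm=pfm, background=bg,
               pseudocount=pseudocount)


def reverse_complement(pfm: PFM) -> PFM:
    """Columns reversed, rows swapped A<->T and C<->G; an involution."""
    return PFM(pfm.counts[::-1, ::-1].copy())


def information_content(pfm: PFM, pseudocount: float = 0.1) -> np.ndarray:
    """Per-column information content in bits: 2 + sum_b p log2 p, in [0, 2]."""
    p = pfm.frequencies(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def consensus(pfm: PFM) -> str:
    """Per-column max-count base; ties broken in A < C < G < T order."""
    return "".join(BASES[int(j)] for j in pfm.counts.argmax(axis=0))
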