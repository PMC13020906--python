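import numpy as np
import pytest

from peakmotif_bench.motifs import PFM, BackgroundModel
from peakmotif_bench.peaks import Peak
from peakmotif_bench.synth import default_motif


@pytest.fixture
def strong_motif() -> PFM:
    """The 12-bp high-information planted test motif (~17 bits)."""
    return default_motif()


@pytest.fixture
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


def random_pfm(rng: np.random.Generator, width: int,
               concentration: float = 1.0) -> PFM:
    """A random PFM with Dirichlet columns scaled to ~100 counts."""
    cols = rng.dirichlet(np.full(4, concentration), size=width).T
    return PFM(cols * 100 + 0.5)


def random_peaks(rng: np.random.Generator, n: int, chroms=("chr1",),
                 genome_length: int = 100_000,
                 max_width: int = 500) -> list[Peak]:
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        width = int(rng.integers(20, max_width))
        start = int(rng.integers(0, genome_length - width))
        peaks.append(Peak(chrom, start, start + width, name=f"p{i}",
                          summit=start + int(rng.integers(width))))
    return peaks


def brute_force_overlap(queries, targets) -> list[bool]:
    """O(n*m) any-overlap oracle (half-open interval test)."""
    out = []
    for q in queries:
        out.append(any(q.chrom == t.chrom and q.start < t.end
                       and t.start < q.end for t in targets))
    return out
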