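import itertools

import numpy as np
import pytest

from peakmotif_bench.errors import EmptyInputError
from peakmotif_bench.formats import Genome
from peakmotif_bench.motifs import (BackgroundModel, PFM, consensus,
                                    pfm_to_pwm, revcomp_seq)
from peakmotif_bench.peaks import Peak
from peakmotif_bench.scanning import (bootstrap_distances, integer_matrix,
                                      null_score_distribution,
                                      scan_sequences, summit_to_motif)

from conftest import random_pfm

BASES = "ACGT"


def enumerate_null(pwm, bg, scale=1000):
    """Exhaustive null oracle: score every possible w-mer, weight by bg."""
    ints = integer_matrix(pwm, scale)
    w = pwm.width
    scores = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(ints[b, j] for j, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    return scores


class TestNullDistribution:
    def test_width_one_pmf_equals_background(self):
        pfm = PFM(np.array([[8.0], [4.0], [2.0], [1.0]]))
        bg = BackgroundModel(np.array([0.4, 0.3, 0.2, 0.1]))
        pwm = pfm_to_pwm(pfm, bg)
        null = null_score_distribution(pwm, bg)
        assert len(null.support) <= 4
        assert null.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        ints = integer_matrix(pwm)
        # bases with equal integer scores pool their background mass
        for s, p in zip(null.support, null.pmf):
            expected = bg.probs[ints[:, 0] == s].sum()
            assert p == pytest.approx(expected, abs=1e-12)

    def test_uniform_pfm_puts_all_mass_at_zero(self):
        pfm = PFM(np.full((4, 4), 25.0))
        null = null_score_distribution(pfm_to_pwm(pfm))
        assert list(null.support) == [0]
        assert null.pmf[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,width", [(s, w) for s in range(3)
                                            for w in (2, 4, 5)])
    def test_matches_exhaustive_enumeration(self, seed, width):
        rng = np.random.default_rng(seed)
        pfm = random_pfm(rng, width)
        bg = BackgroundModel(rng.dirichlet(np.full(4, 5.0)))
        pwm = pfm_to_pwm(pfm, bg)
        null = null_score_distribution(pwm, bg)
        oracle = enumerate_null(pwm, bg.probs)
        assert set(null.support) == set(oracle)
        for s, p in zip(null.support, null.pmf):
            assert p == pytest.approx(oracle[int(s)], abs=1e-12)
        # p-values are exact tail fractions of the enumeration
        for s in null.support:
            tail = sum(p for sc, p in oracle.items() if sc >= s)
            assert null.pvalue(int(s)) == pytest.approx(tail, abs=1e-12)


def naive_scan(pwm, seq, p_threshold, null, scale=1000):
    """Window-by-window scan oracle, scoring directly on both strands."""
    ints = {"+": integer_matrix(pwm, scale),
            "-": integer_matrix(pwm, scale)[::-1, ::-1]}
    w = pwm.width
    hits = []
    for strand, mat in ints.items():
        for i in range(len(seq) - w + 1):
            window = seq[i:i + w]
            if any(c not in BASES for c in window):
                continue
            s = int(sum(mat[BASES.index(c), j]
                        for j, c in enumerate(window)))
            p = float(null.pvalue(s))
            if p <= p_threshold:
                hits.append((i, strand, s, p))
    return sorted(hits)


class TestScan:
    def test_planted_consensus_is_found_on_plus_strand(self, strong_motif):
        pwm = pfm_to_pwm(strong_motif)
        seq = "A" * 40 + consensus(strong_motif) + "C" * 40
        occs = scan_sequences(pwm, [("s", seq)])
        assert any(o.start == 40 and o.strand == "+" for o in occs)

    def test_all_n_sequence_yields_nothing(self, strong_motif):
        pwm = pfm_to_pwm(strong_motif)
        assert scan_sequences(pwm, [("s", "N" * 100)]) == []

    def test_short_sequence_yields_nothing(self, strong_motif):
        pwm = pfm_to_pwm(strong_motif)
        assert scan_sequences(pwm, [("s", "ACGT")]) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_full_scan(self, seed):
        rng = np.random.default_rng(200 + seed)
        pfm = random_pfm(rng, 8, concentration=0.3)
        pwm = pfm_to_pwm(pfm)
        null = null_score_distribution(pwm)
        seq = "".join(rng.choice(list(BASES), size=2000))
        threshold = 1e-3
        occs = scan_sequences(pwm, [("s", seq)], threshold, null=null)
        got = sorted((o.start, o.strand, int(round(o.score * 1000)),
                      o.pvalue) for o in occs)
        expected = naive_scan(pwm, seq, threshold, null)
        assert [(i, st, s) for i, st, s, _ in got] == \
            [(i, st, s) for i, st, s, _ in expected]
        for (_, _, _, pa), (_, _, _, pb) in zip(got, expected):
            assert pa == pytest.approx(pb, rel=1e-12)

    def test_reverse_complement_mirrors_occurrences(self, strong_motif):
        rng = np.random.default_rng(9)
        pwm = pfm_to_pwm(strong_motif)
        seq = "".join(rng.choice(list(BASES), size=500)) \
            + consensus(strong_motif) + "".join(rng.choice(list(BASES), size=50))
        fwd = scan_sequences(pwm, [("s", seq)], 1e-3)
        rev = scan_sequences(pwm, [("s", revcomp_seq(seq))], 1e-3)
        w = pwm.width
        mirrored = sorted((len(seq) - o.start - w,
                           "+" if o.strand == "-" else "-",
                           round(o.score, 9)) for o in rev)
        assert mirrored == sorted((o.start, o.strand, round(o.score, 9))
                                  for o in fwd)


class TestSummitToMotif:
    def _genome_with(self, insert, at, length=400):
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("AT"), size=length)))
        seq[at:at + len(insert)] = insert
        return Genome({"chr1": "".join(seq)})

    def test_summit_at_center_gives_zero(self, strong_motif):
        cons = consensus(strong_motif)
        g = self._genome_with(cons, 200)
        center = 200 + len(cons) // 2
        peak = Peak("chr1", 100, 330, summit=center)
        d = summit_to_motif([peak], pfm_to_pwm(strong_motif), g)
        assert d.mean_absolute == 0.0 and list(d.distances) == [0]

    def test_offset_summit_gives_signed_distance(self, strong_motif):
        cons = consensus(strong_motif)
        g = self._genome_with(cons, 200)
        center = 200 + len(cons) // 2
        peak = Peak("chr1", 100, 330, summit=center + 25)
        d = summit_to_motif([peak], pfm_to_pwm(strong_motif), g)
        assert list(d.distances) == [25] and d.mean_absolute == 25

    def test_nearest_occurrence_chosen(self, strong_motif):
        cons = consensus(strong_motif)
        rng = np.random.default_rng(2)
        filler = "".join(rng.choice(list("AT"), size=500))
        seq = list(filler)
        seq[100:100 + len(cons)] = cons
        seq[300:300 + len(cons)] = cons
        g = Genome({"chr1": "".join(seq)})
        summit = 300 + len(cons) // 2 + 10  # nearer the second instance
        peak = Peak("chr1", 0, 500, summit=summit)
        d = summit_to_motif([peak], pfm_to_pwm(strong_motif), g)
        assert list(d.distances) == [10]

    def test_peaks_without_occurrence_counted_separately(self, strong_motif):
        g = Genome({"chr1": "AT" * 300})
        peak = Peak("chr1", 0, 500, summit=250)
        d = summit_to_motif([peak], pfm_to_pwm(strong_motif), g)
        assert d.n_without_occurrence == 1 and len(d.distances) == 0


class TestBootstrap:
    def test_degenerate_vector_gives_zero_width_ci(self):
        lo, hi = bootstrap_distances([7] * 20, n_boot=200, seed=1)
        assert lo == hi == 7.0

    def test_fixed_seed_reproducible(self):
        d = [0, 3, -5, 10, 2]
        assert bootstrap_distances(d, 500, seed=42) == \
            bootstrap_distances(d, 500, seed=42)

    def test_matches_independent_resampling_oracle(self):
        d = np.array([0, 10, 20])
        lo, hi = bootstrap_distances(d, n_boot=4000, seed=3)
        assert lo < 10 < hi
        # independent oracle implementation with its own rng
        rng = np.random.RandomState(99)
        means = [np.abs(d[rng.randint(0, 3, 3)]).mean()
                 for _ in range(4000)]
        olo, ohi = np.percentile(means, [2.5, 97.5])
        assert lo == pytest.approx(olo, abs=1.5)
        assert hi == pytest.approx(ohi, abs=1.5)

    def test_empty_vector_rejected(self):
        with pytest.raises(EmptyInputError):
            bootstrap_distances([], 100, seed=0)
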