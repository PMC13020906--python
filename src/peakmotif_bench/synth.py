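"""Deterministic synthetic fixtures: genomes, peak files with planted motif
instances, reads with a controlled in-peak fraction, and two-experiment
scenarios with a controlled overlap fraction.

The generators emit the same on-disk formats the readers consume, and every
generator returns a truth table sufficient to compute the expected value of
each downstream metric independently of the pipeline. Everything is
deterministic given the spec seed.

Peaks are laid out on a fixed slot grid (one peak per slot, slots three peak
widths wide), which guarantees non-overlap within an experiment and makes
the two-experiment overlap count exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .formats import Genome, MotifRecord, write_motifs_meme
from .motifs import BASES, PFM, revcomp_seq
from .peaks import GenomicInterval, Peak

__all__ = [
    "SynthSpec",
    "PlantedExperiment",
    "TwoExperiments",
    "default_motif",
    "synth_genome",
    "synth_peaks",
    "synth_reads",
    "synth_two_experiments",
    "write_narrowpeak",
]

_DEFAULT_CONSENSUS = "TGACGTCATGCA"


def default_motif(consensus: str = _DEFAULT_CONSENSUS,
                  dominance: float = 0.91) -> PFM:
    """A high-information 12-bp test motif (~16 bits total by default).

    Each column gives ``dominance`` of its mass to the consensus base and
    splits the rest evenly, mimicking a strong TF motif.
    """
    w = len(consensus)
    counts = np.full((4, w), (1 - dominance) * 100 / 3)
    for j, ch in enumerate(consensus):
        counts[BASES.index(ch), j] = dominance * 100
    return PFM(counts)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic experiment."""

    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.5
    n_peaks: int = 50
    peak_width: int = 200
    planting_fraction: float = 0.8
    summit_jitter_sd: float = 0.0
    motif: PFM = field(default_factory=default_motif)
    frip_target: float = 0.3
    n_reads: int = 1000
    read_length: int = 50
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not (0 < self.gc < 1):
            raise ValidationError("gc must be in (0, 1)")
        if not (0 <= self.planting_fraction <= 1):
            raise ValidationError("planting_fraction must be in [0, 1]")
        if not (0 < self.frip_target <= 1):
            raise ValidationError("frip_target must be in (0, 1]")
        if self.genome_length < self.n_peaks * self.peak_width * 2:
            raise PlacementError(
                "genome_length must be >= 2 * n_peaks * peak_width"
            )
        if self.read_length > self.peak_width:
            raise ValidationError("read_length must not exceed peak_width")


@dataclass
class PlantedExperiment:
    peaks: list[Peak]
    truth: pd.DataFrame      # per-peak planting record
    genome: Genome


@dataclass
class TwoExperiments:
    genome: Genome
    ref: PlantedExperiment
    cmp: PlantedExperiment
    n_common: int


def synth_genome(spec: SynthSpec) -> Genome:
    """A single random chromosome with i.i.d. bases at the given GC content."""
    rng = np.random.default_rng(spec.seed)
    probs = np.array([(1 - spec.gc) / 2, spec.gc / 2,
                      spec.gc / 2, (1 - spec.gc) / 2])
    codes = rng.choice(4, size=spec.genome_length, p=probs)
    seq = np.frombuffer(BASES.encode(), dtype=np.uint8)[codes].tobytes().decode()
    return Genome({spec.chrom: seq})


def _slot_grid(genome_length: int, slot_width: int, peak_width: int):
    n_slots = genome_length // slot_width
    margin = (slot_width - peak_width) // 2
    return n_slots, margin


def _peaks_in_slots(spec: SynthSpec, slots: np.ndarray, slot_width: int,
                    margin: int, prefix: str, shift: int = 0) -> list[Peak]:
    peaks = []
    for i, slot in enumerate(slots):
        start = int(slot) * slot_width + margin + shift
        end = start + spec.peak_width
        peaks.append(Peak(spec.chrom, start, end, name=f"{prefix}_{i}",
                          score=100.0, summit=start + spec.peak_width // 2))
    return peaks


def _plant(genome: Genome, peaks: Sequence[Peak], spec: SynthSpec,
           rng: np.random.Generator) -> pd.DataFrame:
    """Plant one sampled motif instance (centered at summit + jitter) into a
    planting_fraction of peaks; return the per-peak truth table."""
    motif = spec.motif
    w = motif.width
    freqs = motif.frequencies()
    n_plant = int(round(spec.planting_fraction * len(peaks)))
    planted_idx = set(rng.permutation(len(peaks))[:n_plant].tolist())
    rows = []
    for i, p in enumerate(peaks):
        row = {"name": p.name, "chrom": p.chrom, "start": p.start,
               "end": p.end, "summit": p.summit, "planted": i in planted_idx,
               "motif_start": -1, "motif_center": -1, "strand": "."}
        if i in planted_idx:
            jitter = int(round(rng.normal(0.0, spec.summit_jitter_sd))) \
                if spec.summit_jitter_sd > 0 else 0
            center = p.summit + jitter
            inst_start = int(np.clip(center - w // 2, p.start, p.end - w))
            letters = "".join(BASES[rng.choice(4, p=freqs[:, j])]
                              for j in range(w))
            strand = "+" if rng.random() < 0.5 else "-"
            genome.replace(p.chrom, inst_start,
                           letters if strand == "+" else revcomp_seq(letters))
            row.update(motif_start=inst_start,
                       motif_center=inst_start + w // 2, strand=strand)
        rows.append(row)
    return pd.DataFrame(rows)


def synth_peaks(spec: SynthSpec, genome: Genome | None = None,
                path=None) -> PlantedExperiment:
    """Non-overlapping peaks with planted motif instances.

    Planting samples instance letters column-wise from the motif PFM (so
    discovery recovery is a real statistical test), centers each instance at
    the peak summit plus rounded Gaussian jitter, clamped inside the peak,
    and plants on a random strand. Writes a narrowPeak file when ``path`` is
    given. Returns the peaks, the truth table, and the planted genome.
    """
    if genome is None:
        genome = synth_genome(spec)
    rng = np.random.default_rng(spec.seed + 1)
    slot_width = 2 * spec.peak_width
    n_slots, margin = _slot_grid(genome.length(spec.chrom), slot_width,
                                 spec.peak_width)
    if spec.n_peaks > n_slots:
        raise PlacementError(
            f"cannot place {spec.n_peaks} peaks in {n_slots} slots"
        )
    slots = np.sort(rng.choice(n_slots, size=spec.n_peaks, replace=False))
    peaks = _peaks_in_slots(spec, slots, slot_width, margin, "peak")
    truth = _plant(genome, peaks, spec, rng)
    if path is not None:
        write_narrowpeak(peaks, path)
    return PlantedExperiment(peaks=peaks, truth=truth, genome=genome)


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    """Write peaks in MACS narrowPeak (BED6+4) format."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                     f"{p.score:g}\t.\t0\t-1\t-1\t{p.summit - p.start}\n")


def synth_reads(spec: SynthSpec, peaks: Sequence[Peak],
                genome: Genome | None = None,
                path=None) -> list[GenomicInterval]:
    """Reads hitting the FRiP target exactly by construction.

    round(n_reads * frip_target) reads are placed fully inside randomly
    chosen peaks; the remainder fall in inter-peak gaps without touching any
    peak. Writes a BED3 file when ``path`` is given.
    """
    length = genome.length(spec.chrom) if genome is not None \
        else spec.genome_length
    rng = np.random.default_rng(spec.seed + 2)
    rl = spec.read_length
    n_in = int(round(spec.n_reads * spec.frip_target))
    n_out = spec.n_reads - n_in
    reads = []
    peaks = sorted(peaks, key=lambda p: p.start)
    for _ in range(n_in):
        p = peaks[rng.integers(len(peaks))]
        s = int(rng.integers(p.start, p.end - rl + 1))
        reads.append(GenomicInterval(spec.chrom, s, s + rl))
    if n_out:
        gaps = []
        prev = 0
        for p in peaks:
            if p.start - prev >= rl:
                gaps.append((prev, p.start))
            prev = max(prev, p.end)
        if length - prev >= rl:
            gaps.append((prev, length))
        if not gaps:
            raise PlacementError("no inter-peak space left for outside reads")
        weights = np.array([e - s - rl + 1 for s, e in gaps], dtype=float)
        weights /= weights.sum()
        for _ in range(n_out):
            gs, ge = gaps[rng.choice(len(gaps), p=weights)]
            s = int(rng.integers(gs, ge - rl + 1))
            reads.append(GenomicInterval(spec.chrom, s, s + rl))
    if path is not None:
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    return reads


def synth_two_experiments(spec_ref: SynthSpec, spec_cmp: SynthSpec,
                          overlap_fraction: float) -> TwoExperiments:
    """Two peak sets on one genome with an exact mutual overlap count.

    Exactly ``round(overlap_fraction * spec_ref.n_peaks)`` reference peaks
    overlap a comparison peak (a copy shifted by a third of the reference
    peak width); the remaining comparison peaks occupy slots no reference
    peak uses. Each experiment plants its own motif into its own peaks per
    its spec.
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValidationError("overlap_fraction must be in [0, 1]")
    n_common = int(round(overlap_fraction * spec_ref.n_peaks))
    if n_common > spec_cmp.n_peaks:
        raise PlacementError("spec_cmp.n_peaks smaller than the overlap count")
    genome = synth_genome(spec_ref)
    rng = np.random.default_rng(spec_ref.seed + 10)
    width = max(spec_ref.peak_width, spec_cmp.peak_width)
    shift = spec_ref.peak_width // 3
    if shift < 1 or shift >= spec_ref.peak_width:
        raise PlacementError("reference peak width too small to shift copies")
    slot_width = 3 * width + shift
    n_slots, _ = _slot_grid(genome.length(spec_ref.chrom), slot_width, width)
    n_unique_cmp = spec_cmp.n_peaks - n_common
    if spec_ref.n_peaks + n_unique_cmp > n_slots:
        raise PlacementError("not enough slots for both experiments")
    margin = width // 2
    all_slots = rng.permutation(n_slots)
    ref_slots = np.sort(all_slots[:spec_ref.n_peaks])
    cmp_only_slots = np.sort(all_slots[spec_ref.n_peaks:
                                       spec_ref.n_peaks + n_unique_cmp])
    ref_peaks = _peaks_in_slots(spec_ref, ref_slots, slot_width, margin, "ref")
    common_ref_idx = np.sort(rng.permutation(spec_ref.n_peaks)[:n_common])
    cmp_peaks = []
    for j, i in enumerate(common_ref_idx):
        rp = ref_peaks[int(i)]
        start = rp.start + shift
        cmp_peaks.append(Peak(spec_ref.chrom, start,
                              start + spec_cmp.peak_width, name=f"cmp_{j}",
                              score=100.0,
                              summit=start + spec_cmp.peak_width // 2))
    spec_cmp_named = replace(spec_cmp, chrom=spec_ref.chrom)
    cmp_peaks += _peaks_in_slots(spec_cmp_named, cmp_only_slots, slot_width,
                                 margin, "cmpu")
    cmp_peaks.sort(key=lambda p: p.start)
    truth_ref = _plant(genome, ref_peaks, spec_ref,
                       np.random.default_rng(spec_ref.seed + 11))
    truth_cmp = _plant(genome, cmp_peaks, spec_cmp_named,
                       np.random.default_rng(spec_cmp.seed + 12))
    return TwoExperiments(
        genome=genome,
        ref=PlantedExperiment(ref_peaks, truth_ref, genome),
        cmp=PlantedExperiment(cmp_peaks, truth_cmp, genome),
        n_common=n_common,
    )


def write_fixture_files(exp: PlantedExperiment, spec: SynthSpec, out_dir,
                        label: str) -> dict[str, Path]:
    """Write FASTA/narrowPeak/BED/MEME fixture files for one experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "peaks": out / f"{label}.narrowPeak",
        "reads": out / f"{label}_reads.bed",
        "motif": out / f"{label}_motif.meme",
        "truth": out / f"{label}_truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for name in exp.genome.names():
            fh.write(f">{name}\n")
            seq = exp.genome.sequence(name)
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_narrowpeak(exp.peaks, paths["peaks"])
    synth_reads(spec, exp.peaks, exp.genome, path=paths["reads"])
    write_motifs_meme([MotifRecord("planted", f"{label}_planted", spec.motif)],
                      paths["motif"])
    exp.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
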