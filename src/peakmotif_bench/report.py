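"""Benchmark orchestration and the three-section HTML report.

A run compares >= 2 peak files pairwise against a reference (by default the
first file), producing:

  i.   general statistics: FRiP (when alignments are given), peak-width
       summaries, and summit-to-motif distances per supplied motif;
  ii.  known-motif enrichment counts and percentages across the four overlap
       groups of each comparison (when motifs are given);
  iii. de-novo motif discovery per overlap group, the four PCC heatmaps
       (common, unique, cross A, cross B), and the closest known motif per
       discovered motif (when a motif database is given).

Everything is deterministic given the config seed, and results are
independent of the worker count.
"""

from __future__ import annotations

import html as _html
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .discovery import DiscoveredMotif, discover_motifs
from .enrichment import FripResult, enrichment_table, frip, group_enrichment
from .errors import ConfigError
from .formats import (Genome, MotifRecord, read_genome_fasta, read_motifs,
                      read_peaks, read_reads, write_motifs_meme,
                      write_peaks_bed)
from .motifs import PFM, BackgroundModel, consensus, pfm_to_pwm
from .peaks import (Peak, SegregatedPeaks, WidthSummary,
                    extract_peak_sequences, peak_width_summary,
                    segregate_pair)
from .scanning import DEFAULT_P_THRESHOLD, DistanceSummary, summit_to_motif
from .similarity import (ComparisonHeatmaps, build_comparison_heatmaps,
                         nearest_known)

__all__ = [
    "RunConfig",
    "ExperimentStats",
    "PairwiseComparison",
    "ReportBundle",
    "run_benchmark",
    "render_html",
    "save_runfiles",
]

_GROUP_PREFIX = {"common_ref": "mA", "common_cmp": "mB",
                 "unique_ref": "mC", "unique_cmp": "mD"}

_HEATMAP_NOTES = {
    "common": ("High correlation between motifs from the two common groups "
               "indicates that the peaks shared by both experiments are "
               "enriched for the same motifs, i.e. the experiments agree on "
               "the regulatory signal at shared loci."),
    "unique": ("High correlation between motifs from the two unique groups "
               "means both experiments' exclusive peaks still carry similar, "
               "plausibly genuine motifs — each comparison is likely missing "
               "true sites, e.g. through strict peak-calling thresholds."),
    "cross_a": ("Compares motifs from unique reference peaks (mC) to motifs "
                "from common comparison peaks (mB). High values suggest the "
                "reference experiment is the more sensitive one, capturing "
                "extra peaks that carry the shared motif signal."),
    "cross_b": ("Compares motifs from unique comparison peaks (mD) to motifs "
                "from common reference peaks (mA). High values suggest the "
                "reference experiment underrepresents legitimate motifs that "
                "the comparison experiment still detects."),
}


@dataclass
class RunConfig:
    peak_files: list[str]
    genome_fasta: str
    dialects: list[str] = field(default_factory=list)
    exp_labels: list[str] = field(default_factory=list)
    exp_types: list[str] = field(default_factory=list)
    alignment_files: list[str] | None = None
    motif_files: list[str] | None = None
    motif_db: str | None = None
    motif_discovery_count: int = 3
    filter_n: int = 6
    reference_index: int = 0
    workers: int = 1
    seed: int = 0
    out_dir: str = "peakmotif_out"
    save_runfiles: bool = False
    p_threshold: float = DEFAULT_P_THRESHOLD
    bootstrap: int = 0

    def validate(self) -> None:
        n = len(self.peak_files)
        if n < 2:
            raise ConfigError("at least 2 peak files are required")
        if not self.dialects:
            self.dialects = ["macs_narrowpeak"] * n
        if len(self.dialects) == 1:
            self.dialects = self.dialects * n
        if len(self.dialects) != n:
            raise ConfigError("dialects must match peak_files in length")
        if not self.exp_labels:
            self.exp_labels = [f"exp{i + 1}" for i in range(n)]
        if len(self.exp_labels) != n:
            raise ConfigError("exp_labels must match peak_files in length")
        if len(set(self.exp_labels)) != n:
            raise ConfigError("exp_labels must be unique")
        if not self.exp_types:
            self.exp_types = ["unknown"] * n
        if len(self.exp_types) == 1:
            self.exp_types = self.exp_types * n
        if len(self.exp_types) != n:
            raise ConfigError("exp_types must match peak_files in length")
        if self.alignment_files and len(self.alignment_files) != n:
            raise ConfigError("alignment_files must match peak_files in length")
        if not (0 <= self.reference_index < n):
            raise ConfigError(f"reference_index {self.reference_index} out of range")
        if self.workers < 1:
            raise ConfigError("workers must be >= 1")


@dataclass
class ExperimentStats:
    label: str
    exp_type: str
    n_peaks: int
    widths: WidthSummary
    frip: FripResult | None = None
    distances: dict[str, DistanceSummary] = field(default_factory=dict)


@dataclass
class PairwiseComparison:
    ref_label: str
    cmp_label: str
    group_counts: dict[str, int]
    enrichment: pd.DataFrame | None
    discovered: dict[str, list[DiscoveredMotif]]
    heatmaps: ComparisonHeatmaps
    known_matches: pd.DataFrame | None
    segregated: SegregatedPeaks | None = None


@dataclass
class ReportBundle:
    general: list[ExperimentStats]
    comparisons: list[PairwiseComparison]
    seed: int
    config: dict
    version: str = __version__


def infer_motif_format(path: str) -> str:
    """Guess jaspar_pfm vs meme_minimal from the file extension/content."""
    p = Path(path)
    if p.suffix.lower() in (".meme", ".minimal"):
        return "meme_minimal"
    if p.suffix.lower() in (".jaspar", ".pfm"):
        return "jaspar_pfm"
    head = p.read_text()[:2048]
    return "meme_minimal" if "MEME version" in head else "jaspar_pfm"


def _compare_pair(ref_peaks: Sequence[Peak], cmp_peaks: Sequence[Peak],
                  ref_label: str, cmp_label: str, genome: Genome,
                  motif_records: list[MotifRecord] | None,
                  db_records: list[MotifRecord] | None,
                  discovery_count: int, filter_n: int, seed: int,
                  p_threshold: float, keep_segregated: bool
                  ) -> PairwiseComparison:
    seg = segregate_pair(ref_peaks, cmp_peaks, ref_label, cmp_label)
    counts = {g: len(seg.group(g)) for g in SegregatedPeaks.GROUPS}
    enr = None
    if motif_records:
        enr = enrichment_table(
            group_enrichment(seg, motif_records, genome, p_threshold))
    discovered: dict[str, list[DiscoveredMotif]] = {}
    for gi, g in enumerate(SegregatedPeaks.GROUPS):
        seqs = [s for _, s in extract_peak_sequences(seg.group(g), genome)]
        if len(seqs) >= 5:
            found = discover_motifs(seqs, count=discovery_count,
                                    filter_n=filter_n, seed=seed + gi)
        else:
            found = []
        for m in found:
            m.group = g
        discovered[g] = found
    heat = build_comparison_heatmaps(
        [m.pfm for m in discovered["common_ref"]],
        [m.pfm for m in discovered["common_cmp"]],
        [m.pfm for m in discovered["unique_ref"]],
        [m.pfm for m in discovered["unique_cmp"]],
    )
    matches = None
    if db_records:
        rows = []
        for g in SegregatedPeaks.GROUPS:
            for i, m in enumerate(discovered[g]):
                qid = f"{_GROUP_PREFIX[g]}{i + 1}"
                hit = nearest_known(m.pfm, db_records, query_id=qid)
                rows.append({
                    "query": qid, "group": g, "consensus": m.consensus,
                    "best_match": hit.database_id if hit else "-",
                    "match_name": hit.database_name if hit else "-",
                    "pcc": hit.alignment.pcc if hit else np.nan,
                    "strand": hit.alignment.strand if hit else ".",
                })
        matches = pd.DataFrame(rows)
    return PairwiseComparison(
        ref_label=ref_label, cmp_label=cmp_label, group_counts=counts,
        enrichment=enr, discovered=discovered, heatmaps=heat,
        known_matches=matches, segregated=seg if keep_segregated else None,
    )


def _compare_pair_args(args) -> PairwiseComparison:
    return _compare_pair(*args)


def run_benchmark(config: RunConfig) -> ReportBundle:
    """Execute the full benchmark and return all computed results.

    Section ii (known-motif enrichment, summit-to-motif distances) runs iff
    motif files are supplied; the closest-known-motif table iff a motif
    database is supplied; FRiP rows iff alignment files are supplied.
    """
    config.validate()
    genome = read_genome_fasta(config.genome_fasta)
    peak_sets = [read_peaks(p, d)
                 for p, d in zip(config.peak_files, config.dialects)]
    reads = [read_reads(p) for p in config.alignment_files] \
        if config.alignment_files else None
    motif_records = None
    if config.motif_files:
        motif_records = []
        for mf in config.motif_files:
            motif_records.extend(read_motifs(mf, infer_motif_format(mf)))
    db_records = read_motifs(config.motif_db,
                             infer_motif_format(config.motif_db)) \
        if config.motif_db else None

    general = []
    for i, peaks in enumerate(peak_sets):
        stats = ExperimentStats(
            label=config.exp_labels[i], exp_type=config.exp_types[i],
            n_peaks=len(peaks), widths=peak_width_summary(peaks),
        )
        if reads is not None:
            stats.frip = frip(reads[i], peaks)
        if motif_records:
            seqs = [s for _, s in extract_peak_sequences(peaks, genome)]
            background = BackgroundModel.from_sequences(seqs)
            for rec in motif_records:
                pwm = pfm_to_pwm(rec.pfm, background)
                stats.distances[rec.identifier] = summit_to_motif(
                    peaks, pwm, genome, config.p_threshold,
                    n_boot=config.bootstrap, seed=config.seed + i,
                )
        general.append(stats)

    ref_i = config.reference_index
    jobs = []
    for j, i in enumerate(k for k in range(len(peak_sets)) if k != ref_i):
        jobs.append((peak_sets[ref_i], peak_sets[i],
                     config.exp_labels[ref_i], config.exp_labels[i], genome,
                     motif_records, db_records, config.motif_discovery_count,
                     config.filter_n, config.seed + 1000 * (j + 1),
                     config.p_threshold, config.save_runfiles))
    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            comparisons = list(pool.map(_compare_pair_args, jobs))
    else:
        comparisons = [_compare_pair_args(j) for j in jobs]

    cfg_echo = {k: v for k, v in vars(config).items()}
    return ReportBundle(general=general, comparisons=comparisons,
                        seed=config.seed, config=cfg_echo)


# ---------------------------------------------------------------------------
# rendering


def _table(df: pd.DataFrame, floatfmt: str = "{:.3g}") -> str:
    if df is None or df.empty:
        return "<p><em>no data</em></p>"
    shown = df.copy()
    for c in shown.columns:
        if shown[c].dtype.kind == "f":
            shown[c] = shown[c].map(lambda v: floatfmt.format(v)
                                    if pd.notna(v) else "-")
    return shown.to_html(index=False, border=0, classes="tbl")


def _heatmap_table(df: pd.DataFrame) -> str:
    if df.size == 0:
        return "<p><em>empty (a group yielded no motifs)</em></p>"
    cells = ["<table class='heat'><tr><th></th>"]
    cells += [f"<th>{c}</th>" for c in df.columns]
    cells.append("</tr>")
    for idx, row in df.iterrows():
        cells.append(f"<tr><th>{idx}</th>")
        for v in row:
            alpha = max(0.0, min(1.0, (v + 1) / 2))
            cells.append(
                f"<td style='background: rgba(31,119,80,{alpha:.2f})'>"
                f"{v:.2f}</td>")
        cells.append("</tr>")
    cells.append("</table>")
    return "".join(cells)


def render_html(bundle: ReportBundle, out, runfile_links: dict | None = None) -> None:
    """Write a single self-contained HTML report with three sections."""
    e = _html.escape
    parts = [
        "<!doctype html><html><head><meta charset='utf-8'>",
        "<title>Peak-set motif benchmark</title><style>",
        "body{font-family:sans-serif;max-width:70em;margin:2em auto;}",
        ".tbl,.heat{border-collapse:collapse;margin:0.6em 0;}",
        ".tbl td,.tbl th,.heat td,.heat th{border:1px solid #bbb;"
        "padding:3px 8px;text-align:right;}",
        ".note{color:#444;font-size:0.92em;max-width:55em;}",
        "</style></head><body>",
        "<h1>Peak-set motif benchmark report</h1>",
        f"<p class='note'>peakmotif-bench v{e(bundle.version)}; "
        f"seed {bundle.seed}; reference dataset: "
        f"<b>{e(bundle.general[bundle.config.get('reference_index', 0)].label)}"
        f"</b>. Each additional dataset is compared pairwise against the "
        f"reference; peaks are segregated into common/unique groups by "
        f"any-overlap.</p>",
    ]

    parts.append("<h2>1. General statistics</h2>")
    rows = []
    for s in bundle.general:
        rows.append({
            "experiment": s.label, "type": s.exp_type, "peaks": s.n_peaks,
            "mean width (bp)": s.widths.mean,
            "median width (bp)": s.widths.median,
            "FRiP": s.frip.frip if s.frip else np.nan,
        })
    parts.append(_table(pd.DataFrame(rows)))
    dist_rows = []
    for s in bundle.general:
        for mid, d in s.distances.items():
            row = {"experiment": s.label, "motif": mid,
                   "peaks with occurrence": d.n_peaks - d.n_without_occurrence,
                   "peaks without": d.n_without_occurrence,
                   "mean |summit-motif| (bp)": d.mean_absolute}
            if d.bootstrap_ci:
                row["bootstrap 95% CI"] = \
                    f"[{d.bootstrap_ci[0]:.1f}, {d.bootstrap_ci[1]:.1f}]"
            dist_rows.append(row)
    if dist_rows:
        parts.append("<h3>Summit-to-motif distances</h3>")
        parts.append(_table(pd.DataFrame(dist_rows)))

    parts.append("<h2>2. Known motif enrichment</h2>")
    any_enrichment = any(c.enrichment is not None for c in bundle.comparisons)
    if not any_enrichment:
        parts.append("<p class='note'>No motif files supplied; "
                     "section skipped.</p>")
    for c in bundle.comparisons:
        if c.enrichment is None:
            continue
        parts.append(f"<h3>{e(c.ref_label)} vs {e(c.cmp_label)}</h3>")
        counts = ", ".join(f"{g}: {n}" for g, n in c.group_counts.items())
        parts.append(f"<p class='note'>Segregated peak counts — {counts}. "
                     "The Fisher column contrasts each group against its "
                     "unique/common counterpart on the same side (two-sided; "
                     "an addition of this implementation, not part of the "
                     "counts themselves).</p>")
        parts.append(_table(c.enrichment))

    parts.append("<h2>3. Discovered motif analysis</h2>")
    for c in bundle.comparisons:
        parts.append(f"<h3>{e(c.ref_label)} vs {e(c.cmp_label)}</h3>")
        disc_rows = []
        for g, motifs_ in c.discovered.items():
            for i, m in enumerate(motifs_):
                disc_rows.append({"id": f"{_GROUP_PREFIX[g]}{i + 1}",
                                  "group": g, "consensus": m.consensus,
                                  "seed k-mer": m.seed_kmer,
                                  "seed p": m.enrichment_pvalue})
        parts.append(_table(pd.DataFrame(disc_rows)))
        for key, title in (("common", "Common motif comparison"),
                           ("unique", "Unique motif comparison"),
                           ("cross_a", "Cross motif comparison A"),
                           ("cross_b", "Cross motif comparison B")):
            parts.append(f"<h4>{title}</h4>")
            parts.append(f"<p class='note'>{_HEATMAP_NOTES[key]}</p>")
            parts.append(_heatmap_table(getattr(c.heatmaps, key)))
        if c.known_matches is not None:
            parts.append("<h4>Closest known motifs</h4>")
            parts.append(_table(c.known_matches))

    if runfile_links:
        parts.append("<h2>Run files</h2><ul>")
        for name, p in runfile_links.items():
            parts.append(f"<li><a href='{e(str(p))}'>{e(name)}</a></li>")
        parts.append("</ul>")
    parts.append("</body></html>")
    Path(out).write_text("\n".join(parts))


def save_runfiles(bundle: ReportBundle, out_dir) -> dict[str, str]:
    """Export segregated peaks (BED), enrichment tables (TSV), discovered
    motifs (MEME minimal) and heatmaps (TSV) under ``out_dir/runfiles``."""
    root = Path(out_dir) / "runfiles"
    root.mkdir(parents=True, exist_ok=True)
    links: dict[str, str] = {}
    for c in bundle.comparisons:
        tag = f"{c.ref_label}_vs_{c.cmp_label}"
        if c.segregated is not None:
            for g in SegregatedPeaks.GROUPS:
                p = root / f"{tag}.{g}.bed"
                write_peaks_bed(c.segregated.group(g), p)
                links[f"{tag} {g} peaks"] = f"runfiles/{p.name}"
        if c.enrichment is not None:
            p = root / f"{tag}.enrichment.tsv"
            c.enrichment.to_csv(p, sep="\t", index=False)
            links[f"{tag} enrichment"] = f"runfiles/{p.name}"
        records = []
        for g, motifs_ in c.discovered.items():
            for i, m in enumerate(motifs_):
                records.append(MotifRecord(f"{_GROUP_PREFIX[g]}{i + 1}",
                                           m.consensus, m.pfm))
        if records:
            p = root / f"{tag}.discovered.meme"
            write_motifs_meme(records, p)
            links[f"{tag} discovered motifs"] = f"runfiles/{p.name}"
        for key in ("common", "unique", "cross_a", "cross_b"):
            df = getattr(c.heatmaps, key)
            p = root / f"{tag}.heatmap_{key}.tsv"
            df.to_csv(p, sep="\t")
            links[f"{tag} heatmap {key}"] = f"runfiles/{p.name}"
    return links
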