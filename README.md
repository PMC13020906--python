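# peakmotif-bench

Benchmarking epigenomic profiling experiments that target a single
transcription factor (ChIP-Seq, CUT&Tag, TIP-Seq, ...) is awkward because no
"gold standard" peak set exists: when a newer, more sensitive assay reports
many extra peaks, read-count comparisons against ChIP-Seq cannot say whether
those peaks are genuine binding sites or artefacts. `peakmotif-bench` sidesteps
the gold-standard assumption by using **DNA motif content** as the yardstick:
peaks that carry the factor's binding motif are more plausibly genuine,
regardless of which experiment called them.

Given two or more peak files (MACS narrowPeak or SEACR BED) over one genome,
each additional experiment is compared pairwise against a reference. The two
peak sets are segregated by any-overlap into four groups — common-reference,
common-comparison, unique-reference, unique-comparison — and each group is
scored with motif-centric metrics:

* **Known-motif enrichment** — the count and percentage of peaks in each group
  containing at least one significant occurrence of a user-supplied motif
  (e.g. JASPAR CTCF). Occurrences are called by scanning with the log-odds
  matrix `W(b,j) = log2[ (n_bj + c·p_b) / (N_j + c) / p_b ]` (counts `n_bj`,
  pseudocount `c`, background `p_b`), with *exact* p-values from the
  dynamic-programming null distribution of the integer-scaled score under the
  0-order background.
* **Summit-to-motif distance** — signed distance from each peak summit to the
  nearest motif occurrence centre, with mean absolute distance and an
  optional bootstrap CI; measures positional accuracy of the signal.
* **De-novo discovery** — a k-mer-seeded ZOOPS discoverer (dinucleotide-
  preserving shuffle control, one-sided Fisher seed ranking, iterative site
  realignment) run per group, followed by motif-motif comparison via the
  maximum offset-aligned Pearson correlation (PCC) of frequency columns.
  Four heatmaps (common, unique, cross A, cross B) summarise which
  experiment's unique peaks still carry the shared motif signal, and each
  discovered motif is matched to its closest known database motif.
* **General statistics** — FRiP (fraction of reads in peaks) and peak-width
  summaries per experiment.

The output is a single self-contained HTML report; no experiment has to be
declared "correct" up front.

## Worked example

Generate a fully synthetic two-experiment dataset (shared random genome,
planted motif instances, known overlap structure) and benchmark it:

```sh
peakmotif-bench synth --out data --seed 7 --n-peaks 40 --genome-length 300000
peakmotif-bench \
    --peaks data/ref.narrowPeak --peaks data/cmp.narrowPeak \
    --labels REF --labels CMP \
    --genome data/genome.fa \
    --reads data/ref_reads.bed --reads data/cmp_reads.bed \
    --motifs data/ref_motif.meme --motif-db data/ref_motif.meme \
    --discovery-count 2 --seed 7 --out rep --save-runfiles
# -> report written to rep/report.html
```

`rep/report.html` then shows, for this fixture: FRiP 0.40 (REF) vs 0.20
(CMP) — the read in-peak fractions the generator was asked for; 24 of 40
reference peaks in the common group (the requested 60 % overlap); known-motif
enrichment near 100 % in every group (every peak was planted); and
discovered-motif heatmaps whose maxima are ≈1.0 because all four groups
harbour the same planted motif. `rep/runfiles/` holds the segregated peak
BEDs, enrichment TSVs, discovered motifs (MEME minimal) and heatmap TSVs.

The same machinery is importable as a library (`segregate_pair`,
`scan_sequences`, `group_enrichment`, `discover_motifs`, `motif_pcc`,
`run_benchmark`, ...) for use in custom analyses.

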