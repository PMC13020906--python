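import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from peakmotif_bench.cli import main as cli_main
from peakmotif_bench.errors import ConfigError
from peakmotif_bench.report import (RunConfig, render_html, run_benchmark,
                                    save_runfiles)
from peakmotif_bench.synth import (SynthSpec, synth_reads,
                                   synth_two_experiments,
                                   write_fixture_files)


def make_dataset(tmp_path, seed=31, n_peaks=24, overlap=0.5,
                 genome_length=300_000):
    spec_ref = SynthSpec(seed=seed, n_peaks=n_peaks, planting_fraction=1.0,
                         genome_length=genome_length, frip_target=0.8)
    spec_cmp = SynthSpec(seed=seed + 1, n_peaks=n_peaks,
                         planting_fraction=1.0,
                         genome_length=genome_length, frip_target=0.3)
    two = synth_two_experiments(spec_ref, spec_cmp, overlap)
    ref_paths = write_fixture_files(two.ref, spec_ref, tmp_path, "ref")
    cmp_paths = write_fixture_files(two.cmp, spec_cmp, tmp_path, "cmp")
    return two, spec_ref, spec_cmp, ref_paths, cmp_paths


def small_config(tmp_path, **kw):
    _, _, _, ref_paths, cmp_paths = make_dataset(tmp_path)
    defaults = dict(
        peak_files=[str(ref_paths["peaks"]), str(cmp_paths["peaks"])],
        genome_fasta=str(ref_paths["genome"]),
        exp_labels=["REF", "CMP"],
        alignment_files=[str(ref_paths["reads"]), str(cmp_paths["reads"])],
        motif_files=[str(ref_paths["motif"])],
        motif_db=str(ref_paths["motif"]),
        motif_discovery_count=1,
        seed=1,
        out_dir=str(tmp_path / "out"),
    )
    defaults.update(kw)
    return RunConfig(**defaults)


def fingerprint(bundle):
    """Hashable summary of every numeric result in a bundle."""
    out = []
    for s in bundle.general:
        out.append((s.label, s.n_peaks, s.widths.mean, s.widths.median,
                    s.frip.frip if s.frip else None,
                    tuple((k, tuple(d.distances.tolist()))
                          for k, d in s.distances.items())))
    for c in bundle.comparisons:
        out.append((c.ref_label, c.cmp_label, tuple(sorted(
            c.group_counts.items()))))
        if c.enrichment is not None:
            out.append(tuple(map(tuple, c.enrichment.fillna(-1).values)))
        for key in ("common", "unique", "cross_a", "cross_b"):
            out.append(tuple(np.round(
                getattr(c.heatmaps, key).values.ravel(), 12)))
        for g, motifs_ in c.discovered.items():
            out.append((g, tuple((m.seed_kmer, m.consensus)
                                 for m in motifs_)))
    return out


class TestConfigValidation:
    def test_single_peak_file_rejected(self, tmp_path):
        cfg = RunConfig(peak_files=["a"], genome_fasta="g")
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_duplicate_labels_rejected(self):
        cfg = RunConfig(peak_files=["a", "b"], genome_fasta="g",
                        exp_labels=["x", "x"])
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_bad_reference_index_rejected(self):
        cfg = RunConfig(peak_files=["a", "b"], genome_fasta="g",
                        reference_index=5)
        with pytest.raises(ConfigError):
            cfg.validate()


class TestRunBenchmark:
    def test_sections_follow_input_presence(self, tmp_path):
        cfg = small_config(tmp_path, motif_files=None, motif_db=None,
                           alignment_files=None)
        bundle = run_benchmark(cfg)
        assert all(s.frip is None and not s.distances
                   for s in bundle.general)
        assert all(c.enrichment is None and c.known_matches is None
                   for c in bundle.comparisons)
        assert bundle.comparisons[0].heatmaps is not None

    def test_with_motifs_and_reads_all_sections_present(self, tmp_path):
        cfg = small_config(tmp_path)
        bundle = run_benchmark(cfg)
        s = bundle.general[0]
        assert s.frip is not None and s.distances
        assert bundle.general[0].frip.frip > bundle.general[1].frip.frip
        c = bundle.comparisons[0]
        assert c.enrichment is not None and c.known_matches is not None
        # fully planted peaks: common-ref enrichment should be high
        cr = c.enrichment.query("group == 'common_ref'")
        assert (cr["percentage"] >= 80).all()

    def test_three_experiments_two_comparisons(self, tmp_path):
        cfg = small_config(tmp_path)
        third = tmp_path / "third.narrowPeak"
        third.write_text(open(cfg.peak_files[1]).read())
        cfg.peak_files = cfg.peak_files + [str(third)]
        cfg.exp_labels = ["REF", "CMP", "CMP2"]
        cfg.alignment_files = None
        cfg.motif_files = None
        cfg.motif_db = None
        bundle = run_benchmark(cfg)
        assert len(bundle.comparisons) == 2
        assert {c.ref_label for c in bundle.comparisons} == {"REF"}

    def test_deterministic_and_worker_invariant(self, tmp_path):
        cfg = small_config(tmp_path, motif_files=None, motif_db=None,
                           alignment_files=None)
        third = tmp_path / "third.narrowPeak"
        third.write_text(open(cfg.peak_files[1]).read())
        cfg.peak_files = cfg.peak_files + [str(third)]
        cfg.exp_labels = ["REF", "CMP", "CMP2"]
        b1 = run_benchmark(cfg)
        b2 = run_benchmark(cfg)
        assert fingerprint(b1) == fingerprint(b2)
        cfg.workers = 2
        b3 = run_benchmark(cfg)
        assert fingerprint(b1) == fingerprint(b3)


class TestRendering:
    def test_report_contains_three_sections(self, tmp_path):
        cfg = small_config(tmp_path)
        bundle = run_benchmark(cfg)
        out = tmp_path / "report.html"
        render_html(bundle, out)
        html = out.read_text()
        assert "1. General statistics" in html
        assert "2. Known motif enrichment" in html
        assert "3. Discovered motif analysis" in html
        assert "Cross motif comparison B" in html
        assert "mA" in html

    def test_save_runfiles_exports_artifacts(self, tmp_path):
        cfg = small_config(tmp_path, save_runfiles=True)
        bundle = run_benchmark(cfg)
        outdir = tmp_path / "out"
        outdir.mkdir(exist_ok=True)
        links = save_runfiles(bundle, outdir)
        beds = list((outdir / "runfiles").glob("*.bed"))
        assert len(beds) == 4  # one per overlap group
        assert any("heatmap" in str(p)
                   for p in (outdir / "runfiles").glob("*.tsv"))
        assert links


class TestCli:
    def test_help_exits_zero(self):
        result = CliRunner().invoke(cli_main, ["--help"])
        assert result.exit_code == 0
        assert "Benchmark" in result.output

    def test_single_peak_file_is_usage_error(self, tmp_path):
        _, _, _, ref_paths, _ = make_dataset(tmp_path)
        result = CliRunner().invoke(cli_main, [
            "--peaks", str(ref_paths["peaks"]),
            "--genome", str(ref_paths["genome"])])
        assert result.exit_code == 2

    def test_full_synthetic_run_writes_report(self, tmp_path):
        _, _, _, ref_paths, cmp_paths = make_dataset(tmp_path)
        out = tmp_path / "cli_out"
        result = CliRunner().invoke(cli_main, [
            "--peaks", str(ref_paths["peaks"]),
            "--peaks", str(cmp_paths["peaks"]),
            "--labels", "REF", "--labels", "CMP",
            "--genome", str(ref_paths["genome"]),
            "--discovery-count", "1",
            "--seed", "3", "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert (out / "report.html").exists()
        # without --save-runfiles only the report is written
        assert [p.name for p in out.iterdir()] == ["report.html"]

    def test_synth_subcommand(self, tmp_path):
        out = tmp_path / "synth"
        result = CliRunner().invoke(cli_main, [
            "synth", "--out", str(out), "--n-peaks", "10",
            "--genome-length", "50000"])
        assert result.exit_code == 0, result.output
        assert (out / "ref.narrowPeak").exists()
        assert (out / "genome.fa").exists()
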