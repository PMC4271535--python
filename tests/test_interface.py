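"""VCF round-trips, pipeline reproducibility, configuration, CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from denovorate import cli, genotyper, io_vcf, pipeline, simdata
from denovorate.genotyper import UNDEF
from denovorate.pipeline import RunConfig, run_pipeline, summary_from_counts


@pytest.fixture(scope="module")
def variant_calls(small_bundle):
    piles = small_bundle["piles"]
    callset = small_bundle["callset"]
    gcfg = small_bundle["gconfig"]
    calls = []
    cp, cc = piles["chr01"], callset["chr01"]
    for pos0 in np.unique(cc.pair_pos)[:80]:
        call = genotyper.site_call_from_chrom(piles["chr01"], cc,
                                              int(pos0) + 1, gcfg)
        if call.alt is not None and not call.multiallelic:
            calls.append(call)
    assert len(calls) > 30
    return calls


class TestVcfRoundTrip:
    def test_fields_preserved(self, tmp_path, variant_calls, small_bundle):
        samples = small_bundle["piles"].samples
        path = str(tmp_path / "calls.vcf")
        n = io_vcf.write_vcf(variant_calls, path, samples)
        assert n == len(variant_calls)
        back = list(io_vcf.read_vcf(path))
        assert len(back) == n
        for a, b in zip(variant_calls, back):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            np.testing.assert_array_equal(a.genotypes, b.genotypes)
            np.testing.assert_array_equal(a.ref_ad, b.ref_ad)
            np.testing.assert_array_equal(a.alt_ad, b.alt_ad)
            np.testing.assert_array_equal(a.depth, b.depth)
            assert a.lowqual == b.lowqual

    def test_empty_stream_writes_header_only(self, tmp_path):
        path = str(tmp_path / "empty.vcf")
        assert io_vcf.write_vcf([], path, ["mother", "father"]) == 0
        assert list(io_vcf.read_vcf(path)) == []

    def test_undefined_genotype_round_trips_as_missing(self, tmp_path):
        call = genotyper.SiteCall(
            "chr01", 5, "A", "T",
            np.array([1, UNDEF], dtype=np.int8),
            np.array([5, 0]), np.array([5, 0]), np.array([10, 0]),
            60.0, False)
        path = str(tmp_path / "undef.vcf")
        io_vcf.write_vcf([call], path, ["s1", "s2"])
        text = open(path).read()
        assert "./." in text
        back = list(io_vcf.read_vcf(path))[0]
        assert back.genotypes[1] == UNDEF

    def test_lowqual_filter_mapping(self, tmp_path):
        call = genotyper.SiteCall(
            "chr01", 7, "G", "C", np.array([1], dtype=np.int8),
            np.array([3]), np.array([2]), np.array([5]), 12.0, True)
        path = str(tmp_path / "lq.vcf")
        io_vcf.write_vcf([call], path, ["s1"])
        assert "LowQual" in open(path).read()
        assert list(io_vcf.read_vcf(path))[0].lowqual

    def test_missing_format_fields_skip_record(self, tmp_path, caplog):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=LowQual,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "##contig=<ID=chr01,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr01\t10\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/1:9\n")
        path = tmp_path / "noad.vcf"
        path.write_text(text)
        assert list(io_vcf.read_vcf(str(path))) == []

    def test_multiallelic_record_flagged(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "##contig=<ID=chr01,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr01\t10\t.\tA\tT,G\t50\t.\t.\tGT:AD:DP\t0/1:5,3,1:9\n")
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        rec = list(io_vcf.read_vcf(str(path)))[0]
        assert rec.multiallelic


def _tiny_config(seed=7, **sim_kw):
    sim = dict(n_chromosomes=2, chrom_length=4_000, mu_true=2e-5,
               error_rate=0.002, seed=seed)
    sim.update(sim_kw)
    return RunConfig(sim=simdata.SimConfig(**sim),
                     genotyper=genotyper.GenotyperConfig(error_rate=0.002),
                     n_spikes=60, seed=seed, pi=0.024, divergence=0.14,
                     generations_per_year=4)


class TestPipeline:
    def test_reports_are_reproducible(self):
        a = run_pipeline(_tiny_config())
        b = run_pipeline(_tiny_config())
        a.pop("stage_seconds")
        b.pop("stage_seconds")
        assert a == b

    def test_zero_mutation_rate_gives_zero_estimate(self):
        rep = run_pipeline(_tiny_config(mu_true=0.0))
        assert rep["m"] == 0
        assert rep["estimate"]["mu_uncorrected"] == 0.0
        assert rep["estimate"]["ci_uncorrected"][0] == 0.0

    def test_report_serialisable(self, tmp_path):
        rep = run_pipeline(_tiny_config())
        path = tmp_path / "report.json"
        pipeline.write_report(rep, str(path))
        loaded = json.loads(path.read_text())
        assert loaded["m"] == rep["m"]

    def test_config_round_trip(self, tmp_path):
        raw = {"sim": {"n_chromosomes": 2, "chrom_length": 1000, "seed": 5},
               "genotyper": {"error_rate": 0.004},
               "filters": {"min_parent_depth": 12},
               "n_spikes": 25, "seed": 5}
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(raw))
        cfg = RunConfig.from_file(str(path))
        assert cfg.sim.n_chromosomes == 2
        assert cfg.genotyper.error_rate == 0.004
        assert cfg.filters.min_parent_depth == 12
        assert cfg.n_spikes == 25


def test_summary_from_counts_matches_components():
    out = summary_from_counts(9, 2.70e8, 13, 1000, 456, 436,
                              pi=0.024, d=0.14, generations_per_year=4)
    assert out["callable_fraction"] == pytest.approx(0.456)
    assert out["site_individuals"] == pytest.approx(1.60056e9)
    assert out["mu_corrected"] == pytest.approx(
        out["mu_uncorrected"] / out["call_rate"])
    assert out["ne"] == pytest.approx(0.024 / (4 * out["mu_corrected"]))


class TestCli:
    def test_report_json(self):
        runner = CliRunner()
        result = runner.invoke(cli.main, ["report", "--json"])
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert out["m"] == 9
        assert out["mu_corrected"] == pytest.approx(2.9405e-9, rel=1e-3)

    def test_report_human_readable(self):
        result = CliRunner().invoke(cli.main, ["report"])
        assert result.exit_code == 0
        assert "2.9e-09" in result.output
        assert "5 transitions / 4 transversions" in result.output

    def test_simulate_writes_truth(self, tmp_path):
        cfg = {"sim": {"n_chromosomes": 1, "chrom_length": 2000,
                       "mu_true": 1e-4}}
        cfg_path = tmp_path / "c.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        truth_path = tmp_path / "truth.tsv"
        result = CliRunner().invoke(
            cli.main, ["--seed", "3", "simulate", "--config", str(cfg_path),
                       "--truth-out", str(truth_path)])
        assert result.exit_code == 0, result.output
        lines = truth_path.read_text().splitlines()
        assert lines[0].startswith("# seed=3")
        assert lines[1].split("\t") == ["chrom", "pos", "individual", "wt", "mut"]

    def test_run_pipeline_cli(self, tmp_path):
        cfg = {"sim": {"n_chromosomes": 1, "chrom_length": 3000,
                       "mu_true": 2e-5, "error_rate": 0.002},
               "n_spikes": 30}
        cfg_path = tmp_path / "c.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        out_path = tmp_path / "report.json"
        result = CliRunner().invoke(
            cli.main, ["--seed", "2", "run", "--config", str(cfg_path),
                       "--out", str(out_path)])
        assert result.exit_code == 0, result.output
        rep = json.loads(out_path.read_text())
        assert rep["seed"] == 2
        assert "estimate" in rep
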