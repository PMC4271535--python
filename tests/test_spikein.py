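"""Synthetic-mutation planting and the spike-in calibration experiment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denovorate import genotyper, hetdist, mutcall, simdata, spikein
from denovorate.genotyper import HET, GenotyperConfig
from denovorate.mutcall import FilterConfig, classify_site
from denovorate.spikein import evaluate, expected_callable_fraction, plant


class TestPlant:
    def test_counts_conserved(self):
        counts = np.zeros((3, 4), int)
        counts[:, 0] = 20
        rng = np.random.default_rng(0)
        out, base, y = plant(counts, 0, 1, 9, rng)
        assert y == 9
        assert out[1, 0] == 11 and out[1, base] == 9
        assert out.sum() == counts.sum()
        assert counts[1, 0] == 20  # input untouched

    def test_zero_reads_is_identity(self):
        counts = np.full((2, 4), 5, dtype=int)
        out, _, y = plant(counts, 2, 0, 0, np.random.default_rng(1))
        assert y == 0
        np.testing.assert_array_equal(out, counts)

    def test_clamped_to_available_reference_reads(self):
        counts = np.zeros((2, 4), int)
        counts[0, 1] = 3
        out, base, y = plant(counts, 1, 0, 10, np.random.default_rng(2))
        assert y == 3
        assert out[0, 1] == 0 and out[0, base] == 3

    def test_other_individuals_untouched(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 15, size=(5, 4))
        out, _, _ = plant(counts, 0, 2, 4, rng)
        others = [0, 1, 3, 4]
        np.testing.assert_array_equal(out[others], counts[others])

    @given(depth=st.integers(1, 60), y=st.integers(0, 80),
           seed=st.integers(0, 100))
    @settings(max_examples=60, deadline=None)
    def test_depth_invariant_under_any_y(self, depth, y, seed):
        counts = np.zeros((2, 4), int)
        counts[0, 3] = depth
        out, _, y_act = plant(counts, 3, 0, y, np.random.default_rng(seed))
        assert y_act == min(y, depth)
        assert out.sum() == depth

    def test_negative_y_rejected(self):
        with pytest.raises(ValueError):
            plant(np.zeros((1, 4), int), 0, 0, -1, np.random.default_rng(0))


def test_plant_in_piles_is_isolated(small_bundle):
    piles = small_bundle["piles"]
    cp = piles["chr01"]
    before = cp.site_counts(500).copy()
    out, _, _ = spikein.plant_in_piles(piles, "chr01", 500, 3, 5,
                                       np.random.default_rng(0))
    np.testing.assert_array_equal(cp.site_counts(500), before)
    assert out.sum() == before.sum()


class TestEvaluate:
    def test_result_invariants(self, small_bundle):
        res = evaluate(small_bundle["piles"], small_bundle["hetdists"],
                       small_bundle["gconfig"], small_bundle["fconfig"],
                       small_bundle["pedigree"], np.random.default_rng(0),
                       n_spikes=150)
        assert res.n_called <= res.n_callable <= res.n_total == 150
        assert 0 <= res.callable_fraction <= 1

    def test_single_spike(self, small_bundle):
        res = evaluate(small_bundle["piles"], small_bundle["hetdists"],
                       small_bundle["gconfig"], small_bundle["fconfig"],
                       small_bundle["pedigree"], np.random.default_rng(1),
                       n_spikes=1, keep_spikes=True)
        assert res.n_total == 1 and res.n_callable in (0, 1)
        assert len(res.spikes) == 1
        s = res.spikes[0]
        assert s.outcome_called <= s.outcome_callable

    def test_clean_deep_genome_fully_callable(self):
        cfg = simdata.SimConfig(n_chromosomes=2, chrom_length=5_000,
                                mu_true=0.0, error_rate=0.0,
                                maternal_het_density=0.0,
                                paralog_fraction=0.0, mapping_bias=0.0,
                                seed=41)
        piles, ped, _ = simdata.generate(cfg)
        gcfg = GenotyperConfig(error_rate=0.001)
        callset = genotyper.call_genome(piles, gcfg)
        dist, _ = hetdist.build(callset, piles, ped)  # empty -> binomial
        res = evaluate(piles, dist, gcfg, FilterConfig(), ped,
                       np.random.default_rng(2), n_spikes=400)
        assert res.callable_fraction > 0.99
        assert res.call_rate > 0.99

    def test_constructed_uncallable_half(self):
        """Half the genome sits in fully contaminated paralog regions; the
        spike-in callable fraction matches the constructed fraction of
        clean sites."""
        cfg = simdata.SimConfig(n_chromosomes=1, chrom_length=20_000,
                                mu_true=0.0, error_rate=0.0,
                                maternal_het_density=0.0,
                                paralog_fraction=0.5, paralog_alt_rate=1.0,
                                mapping_bias=0.0, seed=43)
        piles, ped, truth = simdata.generate(cfg)
        gcfg = GenotyperConfig(error_rate=0.001)
        callset = genotyper.call_genome(piles, gcfg)
        dist, _ = hetdist.build(callset, piles, ped)
        res = evaluate(piles, dist, gcfg, FilterConfig(), ped,
                       np.random.default_rng(3), n_spikes=800)
        cp = piles["chr01"]
        blocked = 0
        for reg in truth.paralog_regions:
            sel = slice(reg.start - 1, reg.end)
            blocked += int((cp.ref[sel] != simdata.BASE_CODE[reg.base]).sum())
        expected = 1.0 - blocked / cp.length
        se = np.sqrt(expected * (1 - expected) / 800)
        assert abs(res.callable_fraction - expected) < 3 * se


def test_call_rate_agrees_with_truth_recall():
    """The spike-in false-negative estimate matches the directly measured
    recall of planted mutations at callable sites (two binomial SEs)."""
    cfg = simdata.SimConfig(n_chromosomes=2, chrom_length=50_000,
                            mu_true=4e-5, error_rate=0.002,
                            mapping_bias=0.15, seed=47)
    piles, ped, truth = simdata.generate(cfg)
    gcfg = GenotyperConfig(error_rate=0.002)
    fcfg = FilterConfig()
    callset = genotyper.call_genome(piles, gcfg)
    dist, _ = hetdist.build(callset, piles, ped)
    res = evaluate(piles, dist, gcfg, fcfg, ped, np.random.default_rng(5),
                   n_spikes=2000)
    focal = {ped.samples[i] for i in ped.focal_indices}
    n_callable = n_called = 0
    for m in truth.mutations_in(focal):
        cp = piles[m.chrom]
        ind = ped.samples.index(m.individual)
        call = genotyper.call_site(cp.site_counts(m.pos),
                                   int(cp.ref[m.pos - 1]), gcfg)
        cls = classify_site(call, fcfg, ped, exempt=ind)
        if cls.callable:
            n_callable += 1
            n_called += bool(call.genotypes[ind] == HET)
    assert n_callable >= 20
    recall = n_called / n_callable
    se = np.sqrt(res.call_rate * (1 - res.call_rate)
                 * (1 / res.n_callable + 1 / n_callable))
    assert abs(recall - res.call_rate) <= 2 * se + 1e-9


def test_call_rate_decreases_with_mapping_bias():
    """Raising the mapping bias against mutant reads lowers the spike-in
    call rate (the false-negative mechanism the calibration exists for)."""
    rates = []
    for beta in (0.0, 0.35, 0.7):
        cfg = simdata.SimConfig(n_chromosomes=2, chrom_length=15_000,
                                mu_true=0.0, error_rate=0.0,
                                paralog_fraction=0.0, mapping_bias=beta,
                                seed=53)
        piles, ped, _ = simdata.generate(cfg)
        gcfg = GenotyperConfig(error_rate=0.002)
        callset = genotyper.call_genome(piles, gcfg)
        dist, _ = hetdist.build(callset, piles, ped)
        res = evaluate(piles, dist, gcfg, FilterConfig(), ped,
                       np.random.default_rng(7), n_spikes=1500)
        rates.append(res.call_rate)
    assert rates[0] > rates[1] > rates[2]


def test_spike_fraction_matches_exhaustive_expectation(small_bundle):
    """Monte-Carlo spike-in vs the exact per-site expectation of the spiked
    classification outcome."""
    res = evaluate(small_bundle["piles"], small_bundle["hetdists"],
                   small_bundle["gconfig"], small_bundle["fconfig"],
                   small_bundle["pedigree"], np.random.default_rng(8),
                   n_spikes=2500)
    exp = expected_callable_fraction(
        small_bundle["piles"], small_bundle["callset"],
        small_bundle["pedigree"], small_bundle["fconfig"],
        small_bundle["hetdists"], caller_config=small_bundle["gconfig"])
    se = np.sqrt(exp * (1 - exp) / 2500)
    assert abs(res.callable_fraction - exp) < 3 * se


def test_scan_count_matches_spike_fraction_at_low_error(small_bundle):
    """On small genomes the exhaustive callable-site count and the spike-in
    estimate agree within sampling error (the spike exemption makes the two
    estimands differ only through sites dirtied solely by one focal
    individual, negligible at low error rates)."""
    cfg = simdata.SimConfig(n_chromosomes=2, chrom_length=20_000,
                            mu_true=0.0, error_rate=1e-4,
                            paralog_fraction=0.0, mapping_bias=0.0, seed=59)
    piles, ped, _ = simdata.generate(cfg)
    gcfg = GenotyperConfig(error_rate=1e-3)
    fcfg = FilterConfig()
    callset = genotyper.call_genome(piles, gcfg)
    dist, _ = hetdist.build(callset, piles, ped)
    res = evaluate(piles, dist, gcfg, fcfg, ped, np.random.default_rng(9),
                   n_spikes=1200)
    scanres = mutcall.scan(piles, callset, fcfg, ped)
    frac = scanres.n_callable_sites / scanres.n_sites
    se = np.sqrt(frac * (1 - frac) / 1200)
    assert abs(res.callable_fraction - frac) < 3 * se + 0.01


def test_callable_sites_estimate():
    res = spikein.SpikeinResult(1000, 456, 436)
    assert spikein.callable_sites_estimate(res, 2.70e8) == pytest.approx(1.2312e8)
    assert spikein.callable_sites_estimate(
        spikein.SpikeinResult(10, 0, 0), 5e6) == 0
    assert spikein.callable_sites_estimate(
        spikein.SpikeinResult(10, 10, 10), 5e6) == 5e6
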