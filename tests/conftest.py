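import warnings

import numpy as np
import pytest

from denovorate import genotyper, hetdist, mutcall, simdata
from denovorate.simdata import SimConfig, SimulationWarning

warnings.filterwarnings("ignore", category=SimulationWarning)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully featured simulated experiment shared across tests:
    3 x 20 kb chromosomes with SNPs, mutations, paralog regions, sequencing
    error and mapping bias, genotyped with a matched caller."""
    cfg = SimConfig(n_chromosomes=3, chrom_length=20_000, mu_true=2e-5,
                    error_rate=0.002, mapping_bias=0.05, seed=17)
    piles, pedigree, truth = simdata.generate(cfg)
    gcfg = genotyper.GenotyperConfig(error_rate=0.002)
    callset = genotyper.call_genome(piles, gcfg)
    dist, info = hetdist.build(callset, piles, pedigree)
    return {
        "config": cfg,
        "piles": piles,
        "pedigree": pedigree,
        "truth": truth,
        "gconfig": gcfg,
        "fconfig": mutcall.FilterConfig(),
        "callset": callset,
        "hetdists": dist,
        "info": info,
    }


@pytest.fixture(scope="session")
def pedigree30():
    """A bare pedigree (2 parents, 13 focal, 17 bait, one chromosome) for
    constructed-site tests."""
    cfg = SimConfig(n_chromosomes=1, chrom_length=10, mu_true=0.0,
                    error_rate=0.0, paralog_fraction=0.0,
                    maternal_het_density=0.0, seed=0)
    samples, roles = simdata._sample_names(cfg)
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 2, size=(1, 30), dtype=np.int8)
    pat = rng.integers(0, 2, size=(1, 30), dtype=np.int8)
    return simdata.Pedigree(samples, roles, ["chr01"], mat, pat)


def make_site_call(pedigree, *, het=(), alt_reads=(), undefined=(),
                   parent_depths=(30, 30), depth=25, lowqual=False,
                   multiallelic=False, alt="T"):
    """Construct a SiteCall by role: ``het`` lists sample indices called
    heterozygous (with alt reads), ``alt_reads`` lists indices carrying one
    stray alternate read while called hom-ref, ``undefined`` lists indices
    with zero depth."""
    n = pedigree.n_samples
    gt = np.zeros(n, dtype=np.int8)
    depths = np.full(n, depth, dtype=np.int64)
    depths[0], depths[1] = parent_depths
    ref_ad = depths.copy()
    alt_ad = np.zeros(n, dtype=np.int64)
    for i in het:
        gt[i] = genotyper.HET
        alt_ad[i] = depths[i] // 2
        ref_ad[i] = depths[i] - alt_ad[i]
    for i in alt_reads:
        alt_ad[i] = 1
        ref_ad[i] = depths[i] - 1
    for i in undefined:
        gt[i] = genotyper.UNDEF
        depths[i] = 0
        ref_ad[i] = 0
        alt_ad[i] = 0
    return genotyper.SiteCall(
        chrom="chr01", pos=1000, ref="A",
        alt=alt if (alt_ad.sum() or het) else None,
        genotypes=gt, ref_ad=ref_ad, alt_ad=alt_ad, depth=depths,
        site_qual=200.0, lowqual=lowqual, multiallelic=multiallelic)
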