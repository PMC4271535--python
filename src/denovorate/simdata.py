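"""Seeded simulator of a pedigree-sequencing experiment.

Emulates the data structure of a butterfly F2 cross sequenced for direct
mutation-rate estimation: two parents and 30 offspring (13 deeply sequenced
"focal" offspring in which mutations are called, 17 shallower "bait"
offspring used only for filtering), 21 chromosomes that offspring inherit
whole from the achiasmatic mother, segregating maternal SNPs, de novo
mutations planted per gamete, per-base sequencing error, paralog-mismapping
contamination shared across individuals, and a mapping bias against reads
carrying non-reference alleles.

Reads are represented as per-site base counts (the pileup substrate every
downstream computation consumes), not as sequences; there is no alignment
step. Public coordinates are 1-based inclusive, matching VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

BASE_CODE = {b: i for i, b in enumerate("ACGT")}

MOTHER = 0  # the mother's fixed sample column


class SimulationWarning(UserWarning):
    pass


_POISSON_CDF_CACHE: dict[float, np.ndarray] = {}


def _poisson_fixed(lam: float, size, rng: np.random.Generator) -> np.ndarray:
    """Poisson draws for a fixed rate via cached inverse-CDF lookup.

    Exact to the float64 resolution of the CDF; the far tail (mass < 1e-13)
    falls back to the generic sampler. Much faster than rejection sampling
    when the same rate is reused for millions of draws.
    """
    if lam <= 0:
        return np.zeros(size, dtype=np.int64)
    cdf = _POISSON_CDF_CACHE.get(lam)
    if cdf is None:
        from scipy.stats import poisson as _pois

        kmax = int(_pois.isf(1e-13, lam)) + 1
        cdf = _pois.cdf(np.arange(kmax + 1), lam)
        _POISSON_CDF_CACHE[lam] = cdf
    u = rng.random(size)
    x = np.searchsorted(cdf, u, side="right").astype(np.int64)
    tail = x >= cdf.size
    if np.any(tail):
        x[tail] = rng.poisson(lam, size=int(tail.sum()))
    return x


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Depth means are reads/site for the three sequencing roles; ``mu_true`` is
    the per-site per-gamete de novo mutation probability; ``error_rate`` the
    per-base-call error probability; ``mapping_bias`` the probability that a
    read carrying a non-reference allele fails to map (and is lost);
    ``paralog_alt_rate`` the per-read probability that, inside a contaminated
    region, a read is replaced by the region's fixed alternate base in every
    individual.
    """

    n_chromosomes: int = 21
    chrom_length: int = 200_000
    n_focal: int = 13
    n_bait: int = 17
    depth_mean_focal: float = 26.3
    depth_mean_bait: float = 12.7
    depth_mean_parent: float = 33.0
    maternal_het_density: float = 0.02
    mu_true: float = 5e-7
    error_rate: float = 1e-3
    paralog_fraction: float = 0.01
    paralog_alt_rate: float = 0.2
    paralog_region_length: int = 500
    mapping_bias: float = 0.05
    paternal_recombination: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("maternal_het_density", "mu_true", "error_rate",
                     "paralog_fraction", "paralog_alt_rate", "mapping_bias",
                     "paternal_recombination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_chromosomes", "chrom_length", "n_focal", "n_bait",
                     "paralog_region_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("depth_mean_focal", "depth_mean_bait", "depth_mean_parent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_offspring(self) -> int:
        return self.n_focal + self.n_bait

    @property
    def n_samples(self) -> int:
        return 2 + self.n_offspring

    @property
    def n_sites(self) -> int:
        return self.n_chromosomes * self.chrom_length


@dataclass
class Pedigree:
    """Sample roles and whole-chromosome inheritance labels.

    Sample order is fixed: mother, father, focal offspring, bait offspring.
    ``maternal_inheritance[c, j]`` is 0/1 for which maternal homolog offspring
    ``j`` (in offspring order, focal first) received for chromosome ``c``;
    because female meiosis is achiasmatic this label is constant along a
    chromosome and defines that chromosome's segregation pattern.
    """

    samples: list[str]
    roles: dict[str, str]
    chromosomes: list[str]
    maternal_inheritance: np.ndarray  # (n_chrom, n_offspring) int8
    paternal_inheritance: np.ndarray  # (n_chrom, n_offspring) int8

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def focal_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.roles[s] == "focal"])

    @property
    def bait_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.roles[s] == "bait"])

    @property
    def offspring_indices(self) -> np.ndarray:
        return np.arange(2, self.n_samples)

    def chromosome_index(self, chromosome: str) -> int:
        try:
            return self.chromosomes.index(chromosome)
        except ValueError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def segregation_pattern(self, chromosome: str) -> np.ndarray:
        """Maternal homolog label per offspring for one chromosome."""
        return self.maternal_inheritance[self.chromosome_index(chromosome)].copy()


def segregation_pattern(pedigree: Pedigree, chromosome: str) -> np.ndarray:
    return pedigree.segregation_pattern(chromosome)


@dataclass
class SitePile:
    """Read-count pile for one individual at one site."""

    depth: int
    base_counts: np.ndarray  # (4,) counts over A,C,G,T

    def __post_init__(self):
        if self.depth < 0 or int(self.base_counts.sum()) != self.depth:
            raise ValueError("base counts must sum to depth")


class ChromPiles:
    """Per-chromosome pileup: depths plus sparse non-reference counts.

    Most (site, individual) cells contain only reference reads; those are
    implied by ``depth``. Non-reference reads are stored as records
    (pos0, ind, base, count) sorted by (pos0, ind, base), with pos0 0-based.
    """

    def __init__(self, chrom, ref, depth, nr_pos, nr_ind, nr_base, nr_count):
        self.chrom = chrom
        self.ref = ref
        self.depth = depth
        nr_pos = np.asarray(nr_pos, np.int64)
        nr_ind = np.asarray(nr_ind, np.int64)
        nr_base = np.asarray(nr_base, np.int64)
        n = depth.shape[1]
        # merge duplicate (pos, ind, base) contributions into unique records
        key = (nr_pos * n + nr_ind) * 4 + nr_base
        order = np.argsort(key, kind="stable")
        key = key[order]
        cnt = np.asarray(nr_count, np.int64)[order]
        if key.size:
            new = np.empty(key.size, dtype=bool)
            new[0] = True
            np.not_equal(key[1:], key[:-1], out=new[1:])
            seg = np.cumsum(new) - 1
            count = np.bincount(seg, weights=cnt.astype(np.float64))
            ukey = key[new]
        else:
            ukey = key
            count = cnt
        self.nr_pos = (ukey // (4 * n)).astype(np.int64)
        self.nr_ind = ((ukey // 4) % n).astype(np.int32)
        self.nr_base = (ukey % 4).astype(np.int8)
        self.nr_count = count.astype(np.int32)

    @property
    def length(self) -> int:
        return self.ref.shape[0]

    @property
    def n_samples(self) -> int:
        return self.depth.shape[1]

    def site_counts(self, pos: int) -> np.ndarray:
        """Dense (n_samples, 4) base-count matrix at 1-based ``pos``."""
        i = pos - 1
        if not 0 <= i < self.length:
            raise IndexError(f"position {pos} outside chromosome {self.chrom}")
        n = self.n_samples
        counts = np.zeros((n, 4), dtype=np.int32)
        counts[:, self.ref[i]] = self.depth[i]
        lo, hi = np.searchsorted(self.nr_pos, [i, i + 1])
        for r in range(lo, hi):
            ind, b, c = self.nr_ind[r], self.nr_base[r], self.nr_count[r]
            counts[ind, b] += c
            counts[ind, self.ref[i]] -= c
        return counts

    def site_pile(self, pos: int, individual: int) -> SitePile:
        counts = self.site_counts(pos)[individual]
        return SitePile(depth=int(counts.sum()), base_counts=counts)


class PileSet:
    """Whole-experiment pileup: one ChromPiles per chromosome."""

    def __init__(self, chroms: dict[str, ChromPiles], samples: list[str]):
        self.chroms = chroms
        self.samples = samples

    def __getitem__(self, chrom: str) -> ChromPiles:
        return self.chroms[chrom]

    def __iter__(self):
        return iter(self.chroms.values())

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    @property
    def n_sites(self) -> int:
        return sum(cp.length for cp in self)

    def site_counts(self, chrom: str, pos: int) -> np.ndarray:
        return self.chroms[chrom].site_counts(pos)


@dataclass
class PlantedMutation:
    chrom: str
    pos: int  # 1-based
    individual: str
    wt: str
    mut: str


@dataclass
class ParalogRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    base: str   # the region-specific contaminating base

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    planted_mutations: list[PlantedMutation]
    maternal_snps: dict[str, dict[str, np.ndarray]]  # chrom -> pos/alt/carrier
    segregation_patterns: np.ndarray  # (n_chrom, n_offspring)
    paralog_regions: list[ParalogRegion]

    def mutations_in(self, individuals: set[str]) -> list[PlantedMutation]:
        return [m for m in self.planted_mutations if m.individual in individuals]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(m.chrom, m.pos, m.individual, m.wt, m.mut)
             for m in self.planted_mutations],
            columns=["chrom", "pos", "individual", "wt", "mut"],
        )


def _sample_names(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    samples = ["mother", "father"]
    roles = {"mother": "mother", "father": "father"}
    for i in range(config.n_focal):
        name = f"F{i + 1:02d}"
        samples.append(name)
        roles[name] = "focal"
    for i in range(config.n_bait):
        name = f"B{i + 1:02d}"
        samples.append(name)
        roles[name] = "bait"
    return samples, roles


def _spread_errors(true_base, n_err, rng):
    """Distribute error reads uniformly over the 3 bases != true_base.

    Returns (bases (k,3), counts (k,3)) column triplets for k input cells.
    """
    e1 = rng.binomial(n_err, 1.0 / 3.0)
    e2 = rng.binomial(n_err - e1, 0.5)
    e3 = n_err - e1 - e2
    bases = np.stack([(true_base + 1) % 4, (true_base + 2) % 4,
                      (true_base + 3) % 4], axis=-1)
    counts = np.stack([e1, e2, e3], axis=-1)
    return bases, counts


class _RecordSink:
    """Accumulates sparse non-reference records for one chromosome."""

    def __init__(self):
        self.pos, self.ind, self.base, self.count = [], [], [], []

    def add(self, pos, ind, base, count):
        keep = count > 0
        if np.any(keep):
            self.pos.append(np.asarray(pos)[keep])
            self.ind.append(np.asarray(ind)[keep])
            self.base.append(np.asarray(base)[keep])
            self.count.append(np.asarray(count)[keep])

    def arrays(self):
        if not self.pos:
            z = np.array([], dtype=np.int64)
            return z, z.astype(np.int32), z.astype(np.int8), z.astype(np.int32)
        return (np.concatenate(self.pos), np.concatenate(self.ind),
                np.concatenate(self.base), np.concatenate(self.count))


def _simulate_het_pairs(depth, pos, ind, allele1, allele2, cfg, rng, sink):
    """Cells whose true genotype is heterozygous allele1/allele2.

    allele2 is the non-reference allele; reads carrying it are lost with
    probability ``mapping_bias`` (reducing depth), then every surviving read
    miscalls with probability ``error_rate``. Updates ``depth`` in place and
    emits non-reference records.
    """
    d = depth[pos, ind].astype(np.int64)
    a = rng.binomial(d, 0.5)
    if cfg.mapping_bias > 0:
        drop = rng.binomial(a, cfg.mapping_bias)
        a = a - drop
        d = d - drop
        depth[pos, ind] = d
    r = d - a
    eps = cfg.error_rate
    if eps > 0:
        e_r = rng.binomial(r, eps)
        e_a = rng.binomial(a, eps)
    else:
        e_r = np.zeros_like(r)
        e_a = np.zeros_like(a)
    # surviving correctly-called alt reads
    sink.add(pos, ind, allele2, a - e_a)
    for true, errs in ((allele1, e_r), (allele2, e_a)):
        bases, counts = _spread_errors(true, errs, rng)
        for j in range(3):
            b = bases[:, j]
            c = counts[:, j]
            ok = b != allele1  # reference-base "errors" are just ref calls
            sink.add(pos[ok], ind[ok], b[ok], c[ok])


def _simulate_paralog_pairs(depth, pos, ind, ref_base, region_base, cfg, rng, sink):
    """Cells inside paralog regions: true genotype hom-ref, but each read is
    replaced by the region's fixed base with probability paralog_alt_rate."""
    d = depth[pos, ind].astype(np.int64)
    npar = rng.binomial(d, cfg.paralog_alt_rate)
    rest = d - npar
    is_alt = region_base != ref_base
    sink.add(pos[is_alt], ind[is_alt], region_base[is_alt], npar[is_alt])
    eps = cfg.error_rate
    if eps > 0:
        e = rng.binomial(rest, eps)
        bases, counts = _spread_errors(ref_base, e, rng)
        for j in range(3):
            sink.add(pos, ind, bases[:, j], counts[:, j])


def _simulate_chromosome(cfg, chrom_idx, chrom_name, mat_labels, rng,
                         samples, truth_muts, truth_snps, truth_regions):
    L = cfg.chrom_length
    n = cfg.n_samples
    ref = rng.integers(0, 4, size=L, dtype=np.int8)

    # Reads per cell are Poisson(role mean) and each read miscalls with
    # probability eps; by Poisson thinning the error reads are an
    # independent Poisson(mean*eps) component, drawn directly so the bulk
    # error pass needs no separate binomial over every cell.
    eps = cfg.error_rate
    role_sizes = (2, cfg.n_focal, cfg.n_bait)
    role_means = (cfg.depth_mean_parent, cfg.depth_mean_focal,
                  cfg.depth_mean_bait)
    clean = np.concatenate(
        [_poisson_fixed(m * (1.0 - eps), (L, k), rng)
         for m, k in zip(role_means, role_sizes)], axis=1)
    if eps > 0:
        err = np.concatenate(
            [_poisson_fixed(m * eps, (L, k), rng)
             for m, k in zip(role_means, role_sizes)], axis=1)
    else:
        err = np.zeros((L, n), dtype=np.int64)
    depth = clean + err

    # --- paralog regions (placed first; SNPs and mutations avoid them) ---
    region_mask = np.zeros(L, dtype=bool)
    n_regions = int(round(L * cfg.paralog_fraction / cfg.paralog_region_length))
    starts = []
    if n_regions > 0:
        slots = np.arange(0, L - cfg.paralog_region_length,
                          cfg.paralog_region_length * 2)
        if len(slots) >= n_regions:
            starts = np.sort(rng.choice(slots, size=n_regions, replace=False))
        for s in starts:
            e = s + cfg.paralog_region_length
            region_mask[s:e] = True
            rbase = int(rng.integers(0, 4))
            truth_regions.append(
                ParalogRegion(chrom_name, int(s) + 1, int(e), "ACGT"[rbase]))

    free = np.flatnonzero(~region_mask)

    # --- maternal SNPs: mother het ref/alt, father hom-ref ---
    n_snp = rng.binomial(free.size, cfg.maternal_het_density)
    snp_pos = np.sort(rng.choice(free, size=n_snp, replace=False))
    snp_alt = ((ref[snp_pos] + rng.integers(1, 4, size=n_snp)) % 4).astype(np.int8)
    snp_carrier = rng.integers(0, 2, size=n_snp, dtype=np.int8)
    truth_snps[chrom_name] = {
        "pos": snp_pos + 1, "alt": snp_alt, "carrier": snp_carrier,
        "mother_alleles": np.stack([ref[snp_pos], snp_alt], axis=1),
        "father_genotype": np.zeros(n_snp, dtype=np.int8),  # hom-ref
    }

    # --- planted de novo mutations, per offspring, per gamete ---
    snp_set = set(snp_pos.tolist())
    mut_pos_list, mut_ind_list, mut_base_list = [], [], []
    for j, sample_idx in enumerate(range(2, n)):
        k = min(rng.binomial(2 * free.size, cfg.mu_true), free.size)
        if k == 0:
            continue
        ppos = rng.choice(free, size=k, replace=False)
        for p in ppos:
            if p in snp_set:
                continue  # keep generating processes disjoint per cell
            mb = int((ref[p] + rng.integers(1, 4)) % 4)
            mut_pos_list.append(int(p))
            mut_ind_list.append(sample_idx)
            mut_base_list.append(mb)
            truth_muts.append(PlantedMutation(
                chrom_name, int(p) + 1, samples[sample_idx],
                "ACGT"[ref[p]], "ACGT"[mb]))

    # --- assemble heterozygous (site, individual) cells ---
    het_pos = [np.asarray(mut_pos_list, dtype=np.int64)]
    het_ind = [np.asarray(mut_ind_list, dtype=np.int64)]
    het_alt = [np.asarray(mut_base_list, dtype=np.int8)]

    # mother at every SNP
    het_pos.append(snp_pos.astype(np.int64))
    het_ind.append(np.full(n_snp, MOTHER, dtype=np.int64))
    het_alt.append(snp_alt)
    # offspring that inherited the carrier homolog
    for lab in (0, 1):
        offs = 2 + np.flatnonzero(mat_labels == lab)
        sel = np.flatnonzero(snp_carrier == lab)
        if offs.size and sel.size:
            pp = np.repeat(snp_pos[sel], offs.size)
            ii = np.tile(offs, sel.size)
            aa = np.repeat(snp_alt[sel], offs.size)
            het_pos.append(pp.astype(np.int64))
            het_ind.append(ii.astype(np.int64))
            het_alt.append(aa)

    het_pos = np.concatenate(het_pos)
    het_ind = np.concatenate(het_ind)
    het_alt = np.concatenate(het_alt)

    sink = _RecordSink()
    if het_pos.size:
        _simulate_het_pairs(depth, het_pos, het_ind, ref[het_pos], het_alt,
                            cfg, rng, sink)

    # --- paralog cells: every individual at every region site ---
    par_sites = np.flatnonzero(region_mask)
    if par_sites.size:
        rbase_per_site = np.zeros(L, dtype=np.int8)
        for reg in truth_regions:
            if reg.chrom == chrom_name:
                rbase_per_site[reg.start - 1:reg.end] = BASE_CODE[reg.base]
        ppos = np.repeat(par_sites, n)
        pind = np.tile(np.arange(n), par_sites.size)
        _simulate_paralog_pairs(depth, ppos, pind, ref[ppos],
                                rbase_per_site[ppos], cfg, rng, sink)

    # --- bulk sequencing errors for all remaining hom-ref cells ---
    # (special cells re-simulate their own errors above, so their bulk error
    # component is discarded; the cell's total depth stays Poisson(mean))
    if cfg.error_rate > 0:
        if het_pos.size:
            err[het_pos, het_ind] = 0
        if par_sites.size:
            err[par_sites, :] = 0
        nz = np.nonzero(err)
        if nz[0].size:
            e = err[nz]
            tb = ref[nz[0]]
            one = e == 1
            # fast path: a lone error read picks one of the 3 other bases
            b1 = (tb[one] + rng.integers(1, 4, size=int(one.sum()))) % 4
            sink.add(nz[0][one], nz[1][one], b1, e[one])
            many = ~one
            if np.any(many):
                bases, counts = _spread_errors(tb[many], e[many], rng)
                for j in range(3):
                    sink.add(nz[0][many], nz[1][many], bases[:, j],
                             counts[:, j])

    nr_pos, nr_ind, nr_base, nr_count = sink.arrays()
    return ChromPiles(chrom_name, ref, depth.astype(np.int32),
                      nr_pos, nr_ind, nr_base, nr_count)


def generate(config: SimConfig,
             rng: np.random.Generator | None = None
             ) -> tuple[PileSet, Pedigree, TruthSet]:
    """Simulate the full experiment.

    Returns the pileups, the pedigree (with its whole-chromosome inheritance
    labels) and the ground truth (planted mutations, maternal SNPs,
    segregation patterns, paralog regions). Deterministic given
    (config, config.seed); pass ``rng`` to override the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples, roles = _sample_names(config)
    chrom_names = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]

    expected = (2 * config.n_sites * config.mu_true * config.n_offspring)
    if expected < 1.0:
        warnings.warn(
            f"expected planted mutations {expected:.3g} < 1; the simulated "
            "experiment is likely uninformative for rate recovery",
            SimulationWarning, stacklevel=2)

    mat = rng.integers(0, 2, size=(config.n_chromosomes, config.n_offspring),
                       dtype=np.int8)
    pat = rng.integers(0, 2, size=(config.n_chromosomes, config.n_offspring),
                       dtype=np.int8)
    pedigree = Pedigree(samples, roles, chrom_names, mat, pat)

    truth_muts: list[PlantedMutation] = []
    truth_snps: dict[str, dict[str, np.ndarray]] = {}
    truth_regions: list[ParalogRegion] = []
    chroms = {}
    for c, name in enumerate(chrom_names):
        chroms[name] = _simulate_chromosome(
            config, c, name, mat[c], rng, samples,
            truth_muts, truth_snps, truth_regions)

    truth = TruthSet(truth_muts, truth_snps, mat.copy(), truth_regions)
    return PileSet(chroms, samples), pedigree, truth
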