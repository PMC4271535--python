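"""Multi-sample biallelic genotype caller operating on read-count piles.

A deliberately simple maximum-a-posteriori caller standing in for a full
short-read genotyper: per individual the likelihood of (hom-ref, het,
hom-alt) is Binomial(n = ref+alt reads, k = alt reads; p) with
p = (eps, 1/2, 1-eps), combined with the standard diploid variant prior
P(het) = theta, P(hom-alt) = theta/2, P(hom-ref) = 1 - 3*theta/2.

Sites where two or more distinct non-reference bases are each supported by
at least one read are flagged multiallelic and excluded from all downstream
counting. MAP ties break toward hom-ref (conservative). The site quality is
the phred-scaled probability that no individual carries a non-reference
allele; a site is flagged LowQual when that quality falls below the
threshold while some non-reference genotype was called.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import binom

HOMREF, HET, HOMALT, UNDEF = 0, 1, 2, -1

_TABLE_N = 512  # covers depths far beyond the Poisson means used here


@dataclass(frozen=True)
class GenotyperConfig:
    error_rate: float = 1e-3
    heterozygosity: float = 0.01
    lowqual_threshold: float = 30.0

    def __post_init__(self):
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if not 0.0 < self.heterozygosity < 1.0 / 3.0:
            raise ValueError("heterozygosity must be in (0, 1/3)")


@dataclass
class SiteCall:
    """Genotype calls for every sample at one site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str | None
    genotypes: np.ndarray  # (n,) int8: HOMREF/HET/HOMALT/UNDEF
    ref_ad: np.ndarray     # (n,) reads supporting ref
    alt_ad: np.ndarray     # (n,) reads supporting alt
    depth: np.ndarray      # (n,) total reads (all four bases)
    site_qual: float
    lowqual: bool
    multiallelic: bool = False

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


def genotype_likelihoods(ref_count: int, alt_count: int,
                         error_rate: float) -> np.ndarray:
    """Binomial likelihoods of (hom-ref, het, hom-alt) given allele depths."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be >= 0")
    n = ref_count + alt_count
    p = np.array([error_rate, 0.5, 1.0 - error_rate])
    return binom.pmf(alt_count, n, p)


@lru_cache(maxsize=8)
def _tables(error_rate: float, heterozygosity: float):
    """Precomputed MAP genotype and log10 P(hom-ref | data) over (n, k).

    Constant binomial coefficients cancel between genotypes, so posteriors
    are computed from k*log(p) + (n-k)*log(1-p) plus the log prior.
    """
    eps, theta = error_rate, heterozygosity
    n = np.arange(_TABLE_N + 1)[:, None]
    k = np.arange(_TABLE_N + 1)[None, :]
    valid = k <= n
    kk = np.where(valid, k, 0)
    log_prior = np.log([1.0 - 1.5 * theta, theta, 0.5 * theta])
    ll = np.empty((3, _TABLE_N + 1, _TABLE_N + 1))
    for g, p in enumerate((eps, 0.5, 1.0 - eps)):
        ll[g] = kk * np.log(p) + (n - kk) * np.log1p(-p) + log_prior[g]
    # argmax returns the first maximum, so ties resolve hom-ref > het > hom-alt
    gt = np.argmax(ll, axis=0).astype(np.int8)
    from scipy.special import logsumexp

    log10_phomref = (ll[0] - logsumexp(ll, axis=0)) / np.log(10.0)
    gt[~valid] = HOMREF
    log10_phomref[~valid] = 0.0
    return gt, log10_phomref.astype(np.float64)


def _clip_nk(n, k):
    """Fold (n, k) beyond the table range back in, preserving the ratio."""
    n = np.asarray(n, np.int64)
    k = np.asarray(k, np.int64)
    over = n > _TABLE_N
    if np.any(over):
        n = n.copy()
        k = k.copy()
        scale = _TABLE_N / n[over]
        k[over] = np.round(k[over] * scale).astype(np.int64)
        n[over] = _TABLE_N
    return n, k


def map_genotypes(n, k, config: GenotyperConfig) -> np.ndarray:
    """Vectorised MAP genotype for arrays of (used reads, alt reads)."""
    gt_table, _ = _tables(config.error_rate, config.heterozygosity)
    n, k = _clip_nk(n, k)
    gt = gt_table[n, k]
    return np.where(np.asarray(n) == 0, UNDEF, gt).astype(np.int8)


def log10_p_homref(n, k, config: GenotyperConfig) -> np.ndarray:
    _, tab = _tables(config.error_rate, config.heterozygosity)
    n, k = _clip_nk(n, k)
    return tab[n, k]


def call_site(counts: np.ndarray, ref_base: int, config: GenotyperConfig,
              chrom: str = ".", pos: int = 0) -> SiteCall:
    """Call genotypes at one site from a (n_samples, 4) base-count matrix."""
    counts = np.asarray(counts)
    depth = counts.sum(axis=1)
    if depth.sum() == 0:
        n = counts.shape[0]
        return SiteCall(chrom, pos, "ACGT"[ref_base], None,
                        np.full(n, UNDEF, np.int8), np.zeros(n, int),
                        np.zeros(n, int), depth.astype(int), 0.0, False)

    nonref_tot = counts.sum(axis=0)
    nonref_tot = nonref_tot.astype(np.int64)
    nonref_tot[ref_base] = 0
    present = nonref_tot > 0
    multiallelic = int(present.sum()) >= 2
    alt_base = int(np.argmax(nonref_tot)) if present.any() else None

    ref_ad = counts[:, ref_base].astype(np.int64)
    if alt_base is None:
        alt_ad = np.zeros_like(ref_ad)
    else:
        alt_ad = counts[:, alt_base].astype(np.int64)
    n_used = ref_ad + alt_ad
    gt = map_genotypes(n_used, alt_ad, config)
    gt[depth == 0] = UNDEF

    qual = -10.0 * log10_p_homref(n_used, alt_ad, config).sum()
    any_nonref_called = bool(np.any(gt > 0))
    lowqual = bool(qual < config.lowqual_threshold and any_nonref_called)

    return SiteCall(chrom, pos, "ACGT"[ref_base],
                    None if alt_base is None else "ACGT"[alt_base],
                    gt, ref_ad, alt_ad, depth.astype(int),
                    float(qual), lowqual, multiallelic)


class ChromCalls:
    """Vectorised genotype calls for one chromosome.

    Dense per-site arrays (alt base, multiallelic flag, LowQual flag) plus a
    sparse table of the (site, individual) cells holding at least one
    non-reference read; every cell not listed is hom-ref (or undefined at
    depth 0) with zero alt reads.
    """

    def __init__(self, chrom, length, alt_base, multiallelic, lowqual,
                 pair_pos, pair_ind, pair_alt, pair_other, pair_gt):
        self.chrom = chrom
        self.length = length
        self.alt_base = alt_base          # (L,) int8, -1 for invariant sites
        self.multiallelic = multiallelic  # (L,) bool
        self.lowqual = lowqual            # (L,) bool
        self.pair_pos = pair_pos          # (P,) int64, 0-based, sorted
        self.pair_ind = pair_ind          # (P,) int32
        self.pair_alt = pair_alt          # (P,) alt-allele reads
        self.pair_other = pair_other      # (P,) third-base reads
        self.pair_gt = pair_gt            # (P,) int8


def call_chromosome(piles, config: GenotyperConfig) -> ChromCalls:
    """Genotype every site of one chromosome's piles."""
    L = piles.length
    n = piles.n_samples
    pos, ind = piles.nr_pos, piles.nr_ind
    base, cnt = piles.nr_base, piles.nr_count

    # distinct non-reference bases per site and their total support
    if pos.size:
        base_tot = np.bincount(pos * 4 + base, weights=cnt,
                               minlength=L * 4).reshape(L, 4).astype(np.int64)
    else:
        base_tot = np.zeros((L, 4), dtype=np.int64)
    present = base_tot > 0
    n_bases = present.sum(axis=1)
    multiallelic = n_bases >= 2
    alt_base = np.where(n_bases > 0, np.argmax(base_tot, axis=1), -1).astype(np.int8)

    # per-cell aggregates for cells holding non-reference reads; pile
    # records are sorted by (pos, ind), so cell boundaries are run starts
    if pos.size:
        key = pos * n + ind
        new = np.empty(key.size, dtype=bool)
        new[0] = True
        np.not_equal(key[1:], key[:-1], out=new[1:])
        inv = np.cumsum(new) - 1
        ukey = key[new]
        pair_pos = (ukey // n).astype(np.int64)
        pair_ind = (ukey % n).astype(np.int32)
        is_alt = (base == alt_base[pos]).astype(np.float64)
        pair_alt = np.bincount(inv, weights=cnt * is_alt).astype(np.int64)
        pair_nonref = np.bincount(inv, weights=cnt.astype(np.float64)).astype(np.int64)
        pair_other = pair_nonref - pair_alt
        d = piles.depth[pair_pos, pair_ind].astype(np.int64)
        n_used = d - pair_other
        pair_gt = map_genotypes(n_used, pair_alt, config)
    else:
        pair_pos = np.array([], dtype=np.int64)
        pair_ind = np.array([], dtype=np.int32)
        pair_alt = pair_other = pair_pos.copy()
        pair_gt = np.array([], dtype=np.int8)
        n_used = pair_pos

    # LowQual: evaluate the site quality only where a non-ref genotype was
    # called (the flag is defined to be False everywhere else)
    lowqual = np.zeros(L, dtype=bool)
    flag_mask = np.zeros(L, dtype=bool)
    if pair_pos.size:
        flag_mask[pair_pos[pair_gt > 0]] = True
    flagged = np.flatnonzero(flag_mask)
    if len(flagged):
        _, tab = _tables(config.error_rate, config.heterozygosity)
        dsub = piles.depth[flagged, :]
        nclip = np.minimum(dsub, _TABLE_N)
        base_term = tab[nclip, 0].sum(axis=1)
        sel = flag_mask[pair_pos]
        site_of = np.searchsorted(flagged, pair_pos[sel])
        nn, kk = _clip_nk(n_used[sel], pair_alt[sel])
        d0 = np.minimum(piles.depth[pair_pos[sel], pair_ind[sel]], _TABLE_N)
        corr = tab[nn, kk] - tab[d0, 0]
        base_term += np.bincount(site_of, weights=corr, minlength=len(flagged))
        qual = -10.0 * base_term
        lowqual[flagged] = qual < config.lowqual_threshold

    return ChromCalls(piles.chrom, L, alt_base, multiallelic, lowqual,
                      pair_pos, pair_ind, pair_alt, pair_other, pair_gt)


def call_genome(pileset, config: GenotyperConfig) -> dict[str, ChromCalls]:
    return {name: call_chromosome(pileset[name], config)
            for name in pileset.chrom_names}


def site_call_from_chrom(piles, calls: ChromCalls, pos: int,
                         config: GenotyperConfig) -> SiteCall:
    """Materialise a full SiteCall at 1-based ``pos`` from vectorised calls."""
    return call_site(piles.site_counts(pos), int(piles.ref[pos - 1]), config,
                     chrom=piles.chrom, pos=pos)
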