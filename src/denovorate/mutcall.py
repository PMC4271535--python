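"""Six-rule candidate filtering for de novo mutation calling.

A site is callable when every rule passes:

1. not flagged LowQual by the caller;
2. both parents have read depth >= ``min_parent_depth``, are called
   homozygous reference, and carry no alternate-allele reads;
3. no bait offspring carries an alternate-allele read;
4. every focal offspring has a defined genotype;
5. at most ``max_het_focal`` focal offspring are called heterozygous;
6. no focal offspring outside the heterozygous set carries an
   alternate-allele read.

"Carries an alternate-allele read" means allele depth >= 1 for the site's
single alternate base, regardless of the called genotype. Multiallelic sites
(excluded by the genotyper) are recorded under pseudo-rule code 0. No depth
filter is applied to focal or bait offspring. Heterozygous focal offspring
at callable sites become candidate mutations; a site with two heterozygous
focal offspring yields two records flagged as a (premeiotic) cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotyper import HET, UNDEF, ChromCalls, SiteCall

MULTIALLELIC_RULE = 0


@dataclass(frozen=True)
class FilterConfig:
    min_parent_depth: int = 10
    max_het_focal: int = 2

    def __post_init__(self):
        if self.min_parent_depth < 1 or self.max_het_focal < 1:
            raise ValueError("min_parent_depth and max_het_focal must be >= 1")


@dataclass
class SiteClassification:
    callable: bool
    failed_rules: frozenset[int]
    candidate_individuals: list[int] = field(default_factory=list)


@dataclass
class CandidateMutation:
    chrom: str
    pos: int  # 1-based
    individual: str
    wt: str
    mut: str
    mut_reads: int
    wt_reads: int
    parent_depths: tuple[int, int]
    offspring_depth: int
    cluster: bool = False


@dataclass
class ScanResult:
    candidates: list[CandidateMutation]
    n_callable_sites: int
    n_sites: int
    failed_rule_counts: dict[int, int]


def classify_site(call: SiteCall, config: FilterConfig, pedigree,
                  exempt: int | None = None) -> SiteClassification:
    """Classify one site; ``exempt`` removes a focal individual from rules
    4-6 (and lowers the rule-5 threshold by one), the evaluation mode used
    for synthetic spike-in mutations."""
    if call.n_samples != pedigree.n_samples:
        raise ValueError("call and pedigree cover different sample sets")

    focal = [i for i in pedigree.focal_indices if i != exempt]
    bait = pedigree.bait_indices
    gt = call.genotypes
    alt_ad = call.alt_ad
    failed = set()

    if call.multiallelic:
        failed.add(MULTIALLELIC_RULE)
    if call.lowqual:
        failed.add(1)
    pd = (int(call.depth[0]), int(call.depth[1]))
    if (pd[0] < config.min_parent_depth or pd[1] < config.min_parent_depth
            or gt[0] != 0 or gt[1] != 0
            or alt_ad[0] >= 1 or alt_ad[1] >= 1):
        failed.add(2)
    if any(alt_ad[b] >= 1 for b in bait):
        failed.add(3)
    if any(gt[i] == UNDEF for i in focal):
        failed.add(4)
    het = [i for i in focal if gt[i] == HET]
    max_het = config.max_het_focal - (1 if exempt is not None else 0)
    if len(het) > max_het:
        failed.add(5)
    if any(alt_ad[i] >= 1 for i in focal if gt[i] != HET):
        failed.add(6)

    ok = not failed
    return SiteClassification(ok, frozenset(failed), het if ok else [])


def classify_chromosome(piles, calls: ChromCalls, config: FilterConfig,
                        pedigree) -> tuple[np.ndarray, np.ndarray,
                                           list[CandidateMutation]]:
    """Vectorised classification of every site on one chromosome.

    Returns (callable mask (L,), failed-rule bitmask (L,) with bit r set for
    rule r, candidate list). Bit 0 encodes the multiallelic exclusion.
    """
    L = calls.length
    n = pedigree.n_samples
    focal = pedigree.focal_indices
    bait = pedigree.bait_indices

    fail = np.zeros(L, dtype=np.uint16)
    fail |= calls.multiallelic.astype(np.uint16) << MULTIALLELIC_RULE
    fail |= calls.lowqual.astype(np.uint16) << 1

    depth = piles.depth
    r2 = ((depth[:, 0] < config.min_parent_depth)
          | (depth[:, 1] < config.min_parent_depth))

    ppos, pind = calls.pair_pos, calls.pair_ind
    palt, pgt = calls.pair_alt, calls.pair_gt

    def site_mask(sel):
        m = np.zeros(L, dtype=bool)
        m[ppos[sel]] = True
        return m

    role_focal = np.zeros(n, dtype=bool)
    role_focal[focal] = True
    role_bait = np.zeros(n, dtype=bool)
    role_bait[bait] = True
    is_parent = pind < 2
    # a parent cell with non-ref reads either has alt reads, or a non-hom-ref
    # genotype only if it has alt reads; third-base-only cells imply a
    # multiallelic site, already excluded -- checking alt_ad>=1 and gt!=0 is
    # still done explicitly for faithfulness
    r2 |= site_mask(is_parent & ((palt >= 1) | (pgt != 0)))
    fail |= r2.astype(np.uint16) << 2

    is_bait = role_bait[pind]
    fail |= site_mask(is_bait & (palt >= 1)).astype(np.uint16) << 3

    r4 = (depth[:, focal] == 0).any(axis=1)
    is_focal = role_focal[pind]
    r4 |= site_mask(is_focal & (pgt == UNDEF))
    fail |= r4.astype(np.uint16) << 4

    het_sel = is_focal & (pgt == HET)
    het_count = np.bincount(ppos[het_sel], minlength=L)
    fail |= (het_count > config.max_het_focal).astype(np.uint16) << 5

    fail |= site_mask(is_focal & (palt >= 1) & (pgt != HET)).astype(np.uint16) << 6

    ok = fail == 0

    candidates: list[CandidateMutation] = []
    cand_sel = het_sel & ok[ppos]
    for j in np.flatnonzero(cand_sel):
        p = ppos[j]
        i = int(pind[j])
        alt = int(calls.alt_base[p])
        d = depth[p]
        candidates.append(CandidateMutation(
            chrom=calls.chrom, pos=int(p) + 1,
            individual=pedigree.samples[i],
            wt="ACGT"[piles.ref[p]], mut="ACGT"[alt],
            mut_reads=int(palt[j]),
            wt_reads=int(d[i] - palt[j] - calls.pair_other[j]),
            parent_depths=(int(d[0]), int(d[1])),
            offspring_depth=int(d[i]),
            cluster=bool(het_count[p] == 2),
        ))
    return ok, fail, candidates


def scan(pileset, callset: dict[str, ChromCalls], config: FilterConfig,
         pedigree) -> ScanResult:
    """Exhaustively classify every simulated site.

    The resulting callable-site count serves as an oracle against the
    spike-in estimate of the callable fraction.
    """
    candidates: list[CandidateMutation] = []
    n_callable = 0
    n_sites = 0
    rule_counts: dict[int, int] = {r: 0 for r in range(7)}
    for name in pileset.chrom_names:
        piles = pileset[name]
        calls = callset[name]
        ok, fail, cands = classify_chromosome(piles, calls, config, pedigree)
        candidates.extend(cands)
        n_callable += int(ok.sum())
        n_sites += piles.length
        for r in range(7):
            rule_counts[r] += int(((fail >> r) & 1).sum())
    return ScanResult(candidates, n_callable, n_sites, rule_counts)


def site_individuals(n_callable_sites: int, n_focal: int) -> int:
    """Rate denominator: callable sites x focal offspring (2 base copies
    per site-individual are accounted for in the rate itself)."""
    if n_callable_sites < 0 or n_focal < 0:
        raise ValueError("counts must be >= 0")
    return n_callable_sites * n_focal
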