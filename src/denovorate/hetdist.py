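"""Empirical alternate-read-count distributions at known heterozygous sites.

Because female meiosis lacks recombination, every offspring inherits whole
maternal chromosomes, so maternal SNPs on one chromosome segregate with an
identical pattern across the offspring. Sites called heterozygous in the
mother and homozygous in the father whose bait-offspring het/hom vector
exactly matches one chromosome's segregation pattern (in either phase) are
"informative": the heterozygous focal offspring at such sites are known from
the pattern alone, without reference to their sequenced genotypes. Those
focal cells are tabulated into depth-indexed frequency distributions of
non-reference base counts, the empirical input for spike-in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotyper import HET, HOMALT, HOMREF, ChromCalls

DEPTH_CAP = 100


@dataclass
class SegregationPatternSet:
    """One 0/1 label vector over offspring per chromosome."""

    chromosomes: list[str]
    patterns: np.ndarray  # (n_chrom, n_offspring) int8

    @classmethod
    def from_pedigree(cls, pedigree) -> "SegregationPatternSet":
        return cls(list(pedigree.chromosomes),
                   pedigree.maternal_inheritance.copy())

    @property
    def n_offspring(self) -> int:
        return self.patterns.shape[1]


@dataclass
class InformativeSites:
    """Per-chromosome informative sites and their pattern-assigned focal
    heterozygotes."""

    sites: dict[str, np.ndarray]       # chrom -> 1-based positions
    focal_het: dict[str, np.ndarray]   # chrom -> (n_sites, n_focal) bool
    n_ambiguous: int = 0
    n_unmatched: int = 0

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


class HetDepthDistributions:
    """Frequency of alternate-read counts, indexed by read depth 1..cap.

    ``counts[d, y]`` is the number of tabulated focal heterozygote cells with
    read depth d and y non-reference base calls. Depths above the cap, and
    depths never observed, fall back to Binomial(depth, 0.5) when sampled.
    """

    def __init__(self, depth_cap: int = DEPTH_CAP):
        self.depth_cap = depth_cap
        self.counts = np.zeros((depth_cap + 1, depth_cap + 1), dtype=np.int64)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add(self, depths, alt_counts) -> None:
        depths = np.asarray(depths, np.int64)
        alt_counts = np.asarray(alt_counts, np.int64)
        keep = (depths >= 1) & (depths <= self.depth_cap)
        if np.any(alt_counts[keep] > depths[keep]):
            raise ValueError("alternate count exceeds depth")
        np.add.at(self.counts, (depths[keep], alt_counts[keep]), 1)

    def frequency(self, depth: int) -> np.ndarray:
        return self.counts[depth, :depth + 1].copy()

    def mean_alt(self, depth: int) -> float:
        f = self.counts[depth, :depth + 1]
        t = f.sum()
        if t == 0:
            return float("nan")
        return float((np.arange(depth + 1) * f).sum() / t)

    def p_zero(self, depth: int) -> float:
        """P(y == 0) for the given depth, with binomial fallback."""
        if 1 <= depth <= self.depth_cap and self.totals[depth] > 0:
            return float(self.counts[depth, 0] / self.totals[depth])
        return float(0.5 ** depth)

    def sample_alt_count(self, depth: int, rng: np.random.Generator) -> int:
        """Draw y from the empirical distribution at ``depth``; unseen or
        out-of-cap depths draw from Binomial(depth, 0.5)."""
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if depth <= self.depth_cap and self.totals[depth] > 0:
            f = self.counts[depth, :depth + 1]
            return int(rng.choice(depth + 1, p=f / f.sum()))
        return int(rng.binomial(depth, 0.5))


def sample_alt_count(dist: HetDepthDistributions, depth: int,
                     rng: np.random.Generator) -> int:
    return dist.sample_alt_count(depth, rng)


def _pattern_lookup(patterns: SegregationPatternSet, bait_cols: np.ndarray):
    """Map from bait het/hom bit-vector keys to (chrom index, carrier phase).

    Keys matched by more than one (chromosome, phase) are ambiguous and
    dropped. Offspring columns are positions within the offspring vector.
    """
    weights = 1 << np.arange(bait_cols.size, dtype=np.int64)
    table: dict[int, tuple[int, int] | None] = {}
    for c in range(patterns.patterns.shape[0]):
        pat = patterns.patterns[c]
        for phase in (0, 1):
            key = int(((pat[bait_cols] == phase) * weights).sum())
            table[key] = None if key in table else (c, phase)
    return table


def informative_sites(callset: dict[str, ChromCalls],
                      patterns: SegregationPatternSet,
                      pedigree) -> InformativeSites:
    """Identify sites heterozygous in the mother, homozygous in the father,
    whose bait het/hom vector matches exactly one segregation pattern."""
    focal = pedigree.focal_indices
    bait = pedigree.bait_indices
    bait_cols = bait - 2    # offspring-vector positions
    focal_cols = focal - 2
    table = _pattern_lookup(patterns, bait_cols)

    sites: dict[str, np.ndarray] = {}
    focal_het: dict[str, np.ndarray] = {}
    n_amb = 0
    n_unmatched = 0
    for chrom, calls in callset.items():
        ppos, pind, pgt = calls.pair_pos, calls.pair_ind, calls.pair_gt
        L = calls.length

        mother_het = np.zeros(L, dtype=bool)
        father_bad = np.zeros(L, dtype=bool)
        sel_m = (pind == 0)
        mother_het[ppos[sel_m & (pgt == HET)]] = True
        sel_f = (pind == 1)
        father_bad[ppos[sel_f & ~((pgt == HOMREF) | (pgt == HOMALT))]] = True

        cand = np.flatnonzero(mother_het & ~father_bad & ~calls.multiallelic)
        if cand.size == 0:
            sites[chrom] = np.array([], dtype=np.int64)
            focal_het[chrom] = np.zeros((0, focal.size), dtype=bool)
            continue

        # bait genotype matrix at candidate sites; absent cells are hom-ref
        # when covered, undefined at depth 0
        gt_mat = np.zeros((cand.size, bait.size), dtype=np.int8)
        role_bait = np.zeros(pedigree.n_samples, dtype=bool)
        role_bait[bait] = True
        cand_mask = np.zeros(L, dtype=bool)
        cand_mask[cand] = True
        sel_b = role_bait[pind] & cand_mask[ppos]
        rows = np.searchsorted(cand, ppos[sel_b])
        cols = np.searchsorted(bait, pind[sel_b])
        gt_mat[rows, cols] = pgt[sel_b]
        # depth-0 bait cells are absent from the pair table and read as
        # hom-ref here; a truly heterozygous uncovered bait then produces a
        # one-bit mismatch and the site simply fails to match any pattern
        valid = ~(gt_mat == -1).any(axis=1)

        keys = ((gt_mat == HET) @ (1 << np.arange(bait.size, dtype=np.int64)))
        matched_pos = []
        matched_het = []
        for r in np.flatnonzero(valid):
            hit = table.get(int(keys[r]), "missing")
            if hit == "missing":
                n_unmatched += 1
                continue
            if hit is None:
                n_amb += 1
                continue
            c, phase = hit
            matched_pos.append(cand[r] + 1)
            matched_het.append(patterns.patterns[c][focal_cols] == phase)
        sites[chrom] = np.asarray(matched_pos, dtype=np.int64)
        focal_het[chrom] = (np.asarray(matched_het, dtype=bool)
                            if matched_het else
                            np.zeros((0, focal.size), dtype=bool))
    return InformativeSites(sites, focal_het, n_amb, n_unmatched)


def tabulate(info: InformativeSites, pileset, pedigree,
             depth_cap: int = DEPTH_CAP) -> HetDepthDistributions:
    """Tabulate non-reference base counts of pattern-assigned focal
    heterozygotes at informative sites."""
    dist = HetDepthDistributions(depth_cap)
    focal = pedigree.focal_indices
    for chrom, positions in info.sites.items():
        if positions.size == 0:
            continue
        piles = pileset[chrom]
        het = info.focal_het[chrom]
        idx0 = positions - 1
        depth = piles.depth[idx0][:, focal]

        nonref = np.zeros((positions.size, focal.size), dtype=np.int64)
        site_mask = np.zeros(piles.length, dtype=bool)
        site_mask[idx0] = True
        role_focal = np.zeros(piles.n_samples, dtype=bool)
        role_focal[focal] = True
        sel = site_mask[piles.nr_pos] & role_focal[piles.nr_ind]
        rows = np.searchsorted(idx0, piles.nr_pos[sel])
        cols = np.searchsorted(focal, piles.nr_ind[sel])
        np.add.at(nonref, (rows, cols), piles.nr_count[sel])

        dist.add(depth[het], nonref[het])
    return dist


def build(callset, pileset, pedigree, patterns=None,
          depth_cap: int = DEPTH_CAP
          ) -> tuple[HetDepthDistributions, InformativeSites]:
    """informative_sites + tabulate in one step (patterns default to the
    pedigree's known inheritance labels)."""
    if patterns is None:
        patterns = SegregationPatternSet.from_pedigree(pedigree)
    info = informative_sites(callset, patterns, pedigree)
    dist = tabulate(info, pileset, pedigree, depth_cap)
    return dist, info


def infer_patterns(callset: dict[str, ChromCalls], pedigree,
                   n_patterns: int | None = None) -> SegregationPatternSet:
    """Data-driven recovery of segregation patterns (utility).

    Clusters the offspring het/hom vectors of mother-het/father-hom sites by
    exact key frequency and returns the ``n_patterns`` most frequent vectors
    (up to complement). The known-pedigree route is the primary path; this
    exists for crosses where inheritance labels are not recorded.
    """
    if n_patterns is None:
        n_patterns = len(pedigree.chromosomes)
    off = pedigree.offspring_indices
    counts: dict[int, int] = {}
    vecs: dict[int, np.ndarray] = {}
    weights = 1 << np.arange(off.size, dtype=np.int64)
    for chrom, calls in callset.items():
        ppos, pind, pgt = calls.pair_pos, calls.pair_ind, calls.pair_gt
        L = calls.length
        mother_het = np.zeros(L, dtype=bool)
        mother_het[ppos[(pind == 0) & (pgt == HET)]] = True
        cand = np.flatnonzero(mother_het & ~calls.multiallelic)
        if cand.size == 0:
            continue
        gt_mat = np.zeros((cand.size, off.size), dtype=np.int8)
        sel = np.isin(pind, off) & np.isin(ppos, cand)
        rows = np.searchsorted(cand, ppos[sel])
        cols = np.searchsorted(off, pind[sel])
        gt_mat[rows, cols] = pgt[sel]
        het = gt_mat == HET
        keys = het @ weights
        ckeys = (~het) @ weights
        canon = np.minimum(keys, ckeys)
        for k, v in zip(canon, np.where(keys <= ckeys, keys, ckeys)):
            counts[int(k)] = counts.get(int(k), 0) + 1
            vecs.setdefault(int(k), None)
    top = sorted(counts, key=counts.get, reverse=True)[:n_patterns]
    pats = np.array([[int(b) for b in np.binary_repr(k, off.size)[::-1]]
                     for k in top], dtype=np.int8)
    if pats.size == 0:
        pats = np.zeros((0, off.size), dtype=np.int8)
    return SegregationPatternSet(
        [f"cluster{i + 1:02d}" for i in range(len(top))], pats)
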