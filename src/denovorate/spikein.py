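"""Callability and false-negative calibration by synthetic mutation spike-in.

Each spike picks a uniform genomic site and a uniform focal offspring, draws
the number of mutant reads y from the empirical heterozygote distribution
for that individual's depth, converts y reference reads to a random
non-reference base, re-calls the site, and re-applies the six filter rules
with the spiked individual exempted (a real mutation carrier must not block
its own site). The fraction of spikes at callable sites estimates the
callable fraction of the genome; the fraction of callable spikes whose
carrier is called heterozygous estimates the call rate (1 - false-negative
rate). Spikes are planted one at a time into pristine per-site piles, so
they never interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotyper import HET, GenotyperConfig, call_site
from .hetdist import HetDepthDistributions
from .mutcall import FilterConfig, classify_site


@dataclass
class SyntheticMutation:
    chrom: str
    pos: int  # 1-based
    individual: str
    planted_base: str
    y: int
    outcome_callable: bool
    outcome_called: bool


@dataclass
class SpikeinResult:
    n_total: int
    n_callable: int
    n_called: int
    spikes: list[SyntheticMutation] = field(default_factory=list)
    n_clamped: int = 0

    @property
    def callable_fraction(self) -> float:
        return self.n_callable / self.n_total

    @property
    def call_rate(self) -> float:
        """c-hat: fraction of callable synthetic mutations actually called."""
        if self.n_callable == 0:
            return float("nan")
        return self.n_called / self.n_callable


def plant(counts: np.ndarray, ref_base: int, individual: int, y: int,
          rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """Convert y reference reads of one individual to a random non-reference
    base on a copy of a (n_samples, 4) site-count matrix.

    Returns (modified counts, planted base, y actually converted). If y
    exceeds the available reference reads it is clamped (read scarcity at
    low depth); depth is conserved exactly.
    """
    if y < 0:
        raise ValueError("y must be >= 0")
    counts = np.array(counts, copy=True)
    planted = int((ref_base + rng.integers(1, 4)) % 4)
    avail = int(counts[individual, ref_base])
    y_actual = min(y, avail)
    counts[individual, ref_base] -= y_actual
    counts[individual, planted] += y_actual
    return counts, planted, y_actual


def plant_in_piles(pileset, chrom: str, pos: int, individual: int, y: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """Per-site isolated planting: extracts the site's pile from the full
    pile collection and plants on a copy, leaving the originals untouched."""
    piles = pileset[chrom]
    return plant(piles.site_counts(pos), int(piles.ref[pos - 1]),
                 individual, y, rng)


def evaluate(pileset, hetdists: HetDepthDistributions,
             caller_config: GenotyperConfig, filter_config: FilterConfig,
             pedigree, rng: np.random.Generator, n_spikes: int = 1000,
             keep_spikes: bool = False) -> SpikeinResult:
    """Run the spike-in experiment and return callability / call-rate
    estimates."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    chrom_names = pileset.chrom_names
    lengths = np.array([pileset[c].length for c in chrom_names], np.float64)
    chrom_p = lengths / lengths.sum()
    focal = pedigree.focal_indices

    n_callable = 0
    n_called = 0
    n_clamped = 0
    spikes: list[SyntheticMutation] = []
    for _ in range(n_spikes):
        ci = int(rng.choice(len(chrom_names), p=chrom_p))
        chrom = chrom_names[ci]
        piles = pileset[chrom]
        pos = int(rng.integers(1, piles.length + 1))
        ind = int(focal[rng.integers(0, focal.size)])
        depth = int(piles.depth[pos - 1, ind])
        y = hetdists.sample_alt_count(depth, rng) if depth >= 1 else 0

        counts = piles.site_counts(pos)
        ref_base = int(piles.ref[pos - 1])
        if y > 0:
            counts, planted, y_actual = plant(counts, ref_base, ind, y, rng)
            if y_actual < y:
                n_clamped += 1
        else:
            planted, y_actual = -1, 0

        call = call_site(counts, ref_base, caller_config, chrom=chrom, pos=pos)
        cls = classify_site(call, filter_config, pedigree, exempt=ind)
        called = bool(cls.callable and call.genotypes[ind] == HET)
        n_callable += cls.callable
        n_called += called
        if keep_spikes:
            spikes.append(SyntheticMutation(
                chrom, pos, pedigree.samples[ind],
                "ACGT"[planted] if planted >= 0 else ".",
                y_actual, cls.callable, called))
    return SpikeinResult(n_spikes, n_callable, n_called, spikes, n_clamped)


def callable_sites_estimate(result: SpikeinResult, n_sites: int) -> float:
    """Callable-site count implied by the spike-in callable fraction."""
    if result.n_total < 1:
        raise ValueError("empty spike-in result")
    return result.callable_fraction * n_sites


def _quality_band(caller_config: GenotyperConfig,
                  hetdists: HetDepthDistributions, max_depth: int):
    """Per-depth ingredients of the LowQual band at otherwise-clean sites.

    For planted count y at depth d the spiked individual is called non-ref
    for y >= kstar(d); the site is flagged LowQual when the phred quality
    -10*(log10 P(homref | d, y) + sum over others of log10 P(homref | d_j, 0))
    still sits below the threshold. Returns, per depth, kstar, the ascending
    array of -log10 P(homref | d, y), and the cumulative distribution of y.
    """
    from .genotyper import _clip_nk, _tables

    gt_tab, lp_tab = _tables(caller_config.error_rate,
                             caller_config.heterozygosity)
    cap = hetdists.depth_cap
    out = {}
    for d in range(1, max_depth + 1):
        dc, _ = _clip_nk(np.array([d]), np.array([0]))
        dc = int(dc[0])
        ys = np.arange(dc + 1)
        called = gt_tab[dc, ys] != 0
        kstar = int(np.argmax(called)) if called.any() else dc + 1
        neg_q = -lp_tab[dc, ys]  # ascending in y
        if d <= cap and hetdists.totals[d] > 0:
            pmf = hetdists.counts[d, :d + 1] / hetdists.totals[d]
        else:
            from scipy.stats import binom as _binom

            pmf = _binom.pmf(np.arange(d + 1), d, 0.5)
        if pmf.size > dc + 1:  # depth folded into the table range
            pmf = np.concatenate([pmf[:dc], [pmf[dc:].sum()]])
        cdf = np.cumsum(pmf)
        out[d] = (kstar, neg_q, cdf)
    return out


def expected_callable_fraction(pileset, callset, pedigree,
                               filter_config: FilterConfig,
                               hetdists: HetDepthDistributions,
                               caller_config: GenotyperConfig | None = None
                               ) -> float:
    """Exact per-site expectation of the spike-in callable outcome.

    Used as the matched oracle when validating the Monte-Carlo spike-in
    against exhaustive classification. For a uniform (site, focal) choice:

    - sites with any non-reference read in a non-exempt individual, a parent
      below the depth threshold, or an uncovered non-exempt focal offspring
      are never callable under the spike protocol (the planted base either
      collides with the existing alternate base, keeping the offending rule
      violated, or creates a multiallelic site);
    - otherwise-clean sites are callable unless the planted count lands in
      the narrow window where the carrier is called heterozygous with site
      quality still below the LowQual threshold (with ``caller_config`` the
      window probability is computed exactly; without it the window is
      ignored);
    - sites whose only non-reference reads sit in the spiked individual
      itself are callable with probability P(y=0 | depth) + (1-P(y=0))/3
      when those reads are of a single base (the planted base must coincide
      with it to avoid a multiallelic call) and never when they already span
      two bases.
    """
    focal = pedigree.focal_indices
    n_focal = focal.size
    total_weight = 0.0
    n_sites = 0
    band = None
    tab0 = None
    if caller_config is not None:
        from .genotyper import _TABLE_N, _tables

        max_d = max(int(pileset[c].depth.max()) for c in pileset.chrom_names)
        band = _quality_band(caller_config, hetdists, max_d)
        _, lp_tab = _tables(caller_config.error_rate,
                            caller_config.heterozygosity)
        tab0 = lp_tab[:, 0]
        table_n = _TABLE_N
    for chrom in pileset.chrom_names:
        piles = pileset[chrom]
        calls = callset[chrom]
        L = piles.length
        n_sites += L

        par_ok = ((piles.depth[:, 0] >= filter_config.min_parent_depth)
                  & (piles.depth[:, 1] >= filter_config.min_parent_depth))
        focal_def = (piles.depth[:, focal] > 0).sum(axis=1)

        role_focal = np.zeros(piles.n_samples, dtype=bool)
        role_focal[focal] = True
        ppos, pind = calls.pair_pos, calls.pair_ind
        n_dirty = np.zeros(L, dtype=np.int64)
        dirty_nonfocal = np.zeros(L, dtype=bool)
        if ppos.size:
            n_dirty = np.bincount(ppos, minlength=L)
            dirty_nonfocal[ppos[~role_focal[pind]]] = True

        # fully clean sites: weight = number of focal choices that leave all
        # *other* focal offspring covered
        clean = (n_dirty == 0) & par_ok
        clean_full = clean & (focal_def == n_focal)
        total_weight += float((clean & (focal_def == n_focal - 1)).sum())
        if band is None:
            total_weight += float(clean_full.sum()) * n_focal
        else:
            sites = np.flatnonzero(clean_full)
            dsub = np.minimum(piles.depth[sites], table_n)
            t_all = tab0[dsub].sum(axis=1)
            dfoc = dsub[:, focal]
            # others' quality term per (site, focal) cell
            tau = t_all[:, None] - tab0[dfoc]
            c = -caller_config.lowqual_threshold / 10.0 - tau
            weight = np.full(dfoc.shape, 1.0)
            for d in np.unique(dfoc):
                if d < 1:
                    continue  # uncovered cell: y = 0, never flagged
                kstar, neg_q, cdf = band[int(d)]
                sel = dfoc == d
                y_c = np.searchsorted(neg_q, -c[sel], side="left")
                p_hi = np.where(y_c >= 1, cdf[np.minimum(y_c - 1, cdf.size - 1)], 0.0)
                p_lo = cdf[kstar - 1] if kstar >= 1 else 0.0
                p_band = np.clip(p_hi - p_lo, 0.0, 1.0)
                p_band = np.where(y_c <= kstar, 0.0, p_band)
                weight[sel] = 1.0 - p_band
            total_weight += float(weight.sum())

        # sites whose only dirty individual is one focal offspring: callable
        # only when the spike lands on that individual, and then only if the
        # planted base does not create a multiallelic site
        single = ((n_dirty == 1) & ~dirty_nonfocal & par_ok
                  & (focal_def == n_focal))
        if np.any(single) and piles.nr_pos.size:
            # distinct bases per cell come from the per-base pile records
            sel = single[piles.nr_pos] & role_focal[piles.nr_ind]
            key = piles.nr_pos[sel] * piles.n_samples + piles.nr_ind[sel]
            ukey, ucnt = np.unique(key, return_counts=True)  # ucnt = distinct bases
            spos = (ukey // piles.n_samples).astype(np.int64)
            sind = (ukey % piles.n_samples).astype(np.int64)
            one_base = ucnt == 1
            d = piles.depth[spos[one_base], sind[one_base]].astype(np.int64)
            cap = hetdists.depth_cap
            tot = hetdists.totals
            pz_emp = np.where(tot > 0, hetdists.counts[:, 0] / np.maximum(tot, 1),
                              0.5 ** np.arange(cap + 1))
            p0 = np.where(d <= cap, pz_emp[np.minimum(d, cap)], 0.5 ** d)
            p0 = np.where(d < 1, 1.0, p0)
            total_weight += float((p0 + (1.0 - p0) / 3.0).sum())
    return total_weight / (n_focal * n_sites)
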