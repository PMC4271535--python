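# Methods

`denovorate` implements direct estimation of the spontaneous mutation rate
from whole-genome sequencing of two parents and their offspring, in the
design used for *Heliconius melpomene*: a large F2 family split into deeply
sequenced **focal** offspring, in which de novo mutations are called, and
shallower **bait** offspring used purely as a filter against paralog
mismapping. The package contains a calibrated estimator chain (genotype
calling, six-rule site filtering, spike-in calibration of callability and
false negatives, exact Poisson intervals, downstream population-genetic
arithmetic) and a synthetic-data generator that reproduces the statistical
structure the estimator assumes, so that the whole pipeline can be validated
end to end without the original sequencing reads.

## The estimator

Let m be the number of de novo heterozygote events among n_f focal
offspring, and S the number of callable site-individuals (one callable site
in one focal individual). Each site-individual carries two base copies, so

    mu_hat = m / (2 S),        S = f_callable * n_sites * n_f,

where f_callable is estimated by the spike-in experiment (below). The event
count is treated as Poisson; the 95% interval is the exact Garwood interval
obtained from chi-square quantiles, `[chi2(a/2, 2m)/2, chi2(1-a/2, 2m+2)/2]`,
cross-checked in the test suite against independent bisection on the Poisson
tail sums to 1e-9 relative. The false-negative-corrected estimate divides
the point estimate and both bounds by the spike-in call rate c_hat;
uncertainty in c_hat itself is not propagated (its binomial error is
second-order at these counts and is available from the spike-in result).

Derived quantities use standard neutral-theory identities: Ne = pi/(4 mu)
from 4-fold degenerate diversity, and divergence time t = d/(2 mu)
generations from diversity-corrected neutral divergence, converted to years
by a generations-per-year scalar.

Two printed-rounding quirks of the original report are worth noting for
anyone comparing output digit by digit: dividing the *unrounded* upper CI
bound by c_hat gives 5.6e-9 (the report divided the rounded 5.3e-9,
printing 5.5e-9), and d/(2 mu) with the unrounded corrected rate gives
23.8M generations (printed: 23M). The package always reports unrounded
values; `estimate.round_sig` is a pure presentation layer.

## Genotype calling

The caller is a deliberately minimal stand-in for a short-read multi-sample
genotyper, operating on per-site read counts. Per individual,
L(g) = Binomial(n = ref+alt reads, k = alt reads; p_g) with
p = (eps, 1/2, 1-eps) for hom-ref/het/hom-alt, combined with the diploid
variant prior P(het) = theta, P(hom-alt) = theta/2 (theta defaults to 0.01,
the heterozygosity prior the original pipeline used; calls at these depths
are insensitive to it). MAP ties resolve toward hom-ref. The alternate base
is the best-supported non-reference base across all samples; sites where two
distinct non-reference bases each have read support are flagged multiallelic
and excluded from all downstream counting (a conservative choice — a true
mutation colliding with a stray error read is discarded, and the spike-in
calibration absorbs exactly this loss into the callable fraction). Site
quality is the phred-scaled probability that no sample carries a
non-reference allele, computed from the per-sample posteriors; the LowQual
flag is set when that quality falls below 30 while some non-reference
genotype was called, emulating the flag the first filter rule consumes.

## Filtering rules

A site is callable iff: (1) not LowQual; (2) both parents have depth >= 10,
are called hom-ref, and have zero alternate-allele reads; (3) no bait
offspring has an alternate-allele read; (4) all focal genotypes are defined;
(5) at most two focal offspring are called heterozygous; (6) no other focal
offspring has an alternate-allele read. "Alternate-allele read" means
allele depth >= 1 for the site's single alternate base regardless of called
genotype; third-base reads are handled by the multiallelic exclusion. There
is deliberately no depth filter on offspring. Heterozygous focal offspring
at callable sites are the candidates; two sharing a site are emitted as a
flagged premeiotic-cluster pair (counted as two events in the rate).

Sites excluded because a parent carries alternate alleles remove mutations
and callable sites proportionally, so no compensation is applied.

## Heterozygote read-count distributions

Lepidopteran females are achiasmatic: offspring inherit whole maternal
chromosomes, so maternal SNPs on one chromosome share a single segregation
pattern across the offspring. Sites called het in the mother and hom in the
father whose bait het/hom vector exactly matches one chromosome's pattern
(in either phase) identify focal heterozygotes *from the pattern alone*,
independent of their own reads. Their non-reference read counts, tabulated
by depth 1..100, form the empirical distributions used by the spike-in;
they embody whatever reference bias the data carry (mean alternate count
(1-beta)/(2-beta) * depth under read-loss bias beta, rather than depth/2).
Ambiguously matching sites are dropped and counted. Depths above 100 or
never observed fall back to Binomial(depth, 1/2). A shallow het bait whose
balanced allele draw happens to look homozygous breaks the exact match and
loses the site (~10% of sites at bait depth ~13); this thins the tabulation
without biasing it, because focal read counts are independent of bait reads.

## Spike-in calibration

Each of n_spikes (default 1000) synthetic mutations picks a uniform genomic
site and focal individual, draws y from the empirical distribution at that
individual's depth, converts y reference reads to one random non-reference
base, re-calls the site, and re-applies the rules with the spiked individual
exempted from rules 4-6 (rule 5's threshold drops by one) — a mutation
carrier must not veto its own site. The callable fraction of spikes
estimates f_callable; the fraction of callable spikes whose carrier is
called het estimates c_hat. Spikes are planted one at a time into pristine
per-site piles, so they never interact; with a count substrate this per-site
isolation is exact.

`spikein.expected_callable_fraction` computes the exact per-site expectation
of the spike outcome (used as the deterministic oracle in validation): sites
with any non-reference read outside the spiked individual, an under-depth
parent, or an uncovered other focal are never callable (the planted base
either collides with the existing alternate base, keeping the offending rule
violated, or makes the site multiallelic); clean sites are callable up to a
small quality-flag band; sites dirtied only by the spiked individual itself
are callable with probability P(y=0) + (1-P(y=0))/3.

## The simulator

The generator emulates the cross at desk scale with defaults frozen to the
study design: 21 chromosomes, 2 parents at mean depth 33, 13 focal
offspring at 26.3 and 17 bait offspring at 12.7 (all Poisson), whole-
chromosome maternal and paternal inheritance (a paternal recombination
option exists, default off, since no implemented statistic is sensitive to
it). Reads are per-site base counts; no read sequences or alignment exist,
because every downstream computation consumes genotype calls and allele
depths. Per cell:

- **maternal SNPs** (density 0.02/bp, matching ~2% heterozygosity): mother
  het ref/alt, father hom-ref; offspring het iff they inherited the carrier
  homolog;
- **de novo mutations**: Bernoulli(mu_true) per site per gamete in every
  offspring (default 5e-7, the desk-scale rate that makes a 21 x 200 kb
  experiment informative; the real rate would yield well under one event);
- **sequencing error**: each read miscalls to a uniform other base with
  probability eps (default 1e-3). Errors are drawn by Poisson thinning —
  the error reads of a Poisson(lambda) cell are an independent
  Poisson(lambda*eps) component — which is exact and avoids a per-cell
  binomial pass;
- **mapping bias**: any read carrying a non-reference allele (SNP alt or
  planted mutant) is lost with probability beta (default 0.05), shrinking
  depth. This is what shifts the heterozygote distributions below 1/2 and
  creates the false negatives the spike-in measures;
- **paralog mismapping**: ~1% of the genome lies in 500 bp regions where
  every individual's reads are replaced by a fixed region-specific base
  with probability 0.2 — the shared-contamination signature the bait rule
  removes.

SNPs and planted mutations are placed outside paralog regions so each cell
has a single generating process; at the default 1% paralog fraction this
changes effective densities by under 1% and is noted here once. Two
simultaneous mutations at one site in different offspring with different
mutant bases make the site multiallelic and are correctly lost.

Coordinates are 1-based inclusive. Identical config and seed give
byte-identical output; the depth sampler uses a cached inverse-CDF lookup
(exact to the float64 CDF; tail mass < 1e-13 falls back to the generic
sampler).

What the generator does *not* emulate: indels and structural variants, GC
or positional coverage waves, overdispersed (negative-binomial) depth,
base-quality miscalibration, alignment around the mutation site itself
(re-alignment losses in the real pipeline are one reason its call rate was
96% while matched-error simulations sit near 99%). Passing tests therefore
demonstrate the correctness and calibration of the *estimator chain*, not
the error profile of any particular sequencing platform.

## Validation experiment sizes

The acceptance-level checks run at sizes chosen to keep the full suite
within a coffee break on one core: parameter recovery uses 50 seeds of a
21 x 200 kb genome at eps = 0.005, beta = 0.05, mu_true = 5e-7 with 1000
spikes per seed (the corrected estimator's mean lands within two
Monte-Carlo SEs of truth; with ~2.5 detected events per seed the estimator
is noisy per genome but unbiased in mean); the spike-vs-exhaustive
comparison pools those same 50,000 spikes against the exact expectation;
interval coverage uses 500 Poisson draws at lambda = 9. The acceptance
script repeats the recovery at 10 seeds by default (`--sim-seeds` scales
it).

## Numerical and design choices

- Genotype tables (MAP decision and log-posterior of hom-ref) are
  precomputed over (n, k) up to n = 512 and cached per (eps, theta);
  deeper cells fold back proportionally.
- The exact-CI bisection brackets lambda in [1e-12, 10(k+10)] with Brent's
  method at 1e-14 relative tolerance.
- Ties: MAP genotype prefers hom-ref, then het; the alternate base prefers
  the lower base index on exact count ties (only reachable at multiallelic
  sites, which are excluded anyway).
- Empty spike-in calibration (no callable spikes) leaves the estimate
  uncorrected and reports c_hat as NaN rather than failing.
- Degenerate inputs: all-zero-depth sites give all-undefined calls; zero
  mutation events give a zero rate with an exact zero lower bound;
  expected planted mutations below one trigger a warning, not an error.

## Known limitations

- The callable fraction is extremely sensitive to the error rate (any
  stray read disqualifies a site under rules 2/3/6 or the multiallelic
  exclusion): ~46% of sites are callable at eps = 1e-3 but only ~4% at
  eps = 5e-3. This mirrors the design's reliance on aggressive filtering
  and is the main reason real pipelines pre-filter reads by base quality.
- c_hat from matched-error simulation is optimistic relative to real data
  (no re-alignment loss; see above).
- The pattern-inference utility (`hetdist.infer_patterns`) is a frequency
  clustering aid, not a replacement for known cross structure, and is not
  on the validated path.
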