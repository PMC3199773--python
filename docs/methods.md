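# Methods

This note documents the models behind `dzscan`, the conventions and defaults
that matter, the numerical choices made where the design was open, and what
the synthetic-data experiments do and do not demonstrate.

## Data model and filters

A locus is a FASTA multiple alignment of ingroup accessions plus outgroup
records (ids prefixed `OUT|species`), with exon intervals and reading-frame
phases from an annotation table and accession → ancestry-group labels from a
metadata table. Accessions are naturally inbred lines and are treated as
haploid genomes throughout.

Filtering happens at three levels, in this order:

1. **Sequences**: a sequence is removed when its defined length (non-N,
   non-gap) is strictly below 25% of the longest sequence's defined length;
   the threshold is 60% for synonymous/non-synonymous analyses. Sequences
   exactly at the threshold are retained.
2. **Outgroup**: the designated default outgroup species is used unless its
   defined length is strictly below 75% of the longest sequence's, in which
   case the longest alternative outgroup is used; with no admissible
   outgroup the locus is *unoriented* (D is still computed; θ_H, θ_L, Z and
   the joint test are NA).
3. **Sites**: the default mask keeps alignment columns with ≥ 70% defined
   data among retained ingroup sequences; the strict mask (coding
   classification, recombination) keeps only complete columns. Gaps count
   as missing. At kept biallelic columns the ancestral state is the
   outgroup base when it is defined and matches one of the ingroup alleles;
   otherwise the site is unoriented (counted in S and π, excluded from the
   oriented spectrum).

Internally coordinates are 0-based half-open; all written reports are
1-based closed.

**Coding sites.** Synonymous/non-synonymous site totals use the unweighted
Nei–Gojobori method: per codon, the fraction of the three possible changes
at each position that preserve the amino acid, averaged over retained
sequences; changes to stop codons count as non-synonymous and stop codons
are excluded. Codon pairs differing at several positions are decomposed
over minimal-change pathways (orderings of the differing positions),
excluding pathways through stops when any stop-free pathway exists, and a
position is labelled synonymous when its pathway-averaged synonymous weight
is ≥ 0.5. Codons with more than two observed states are compared via their
two most frequent codons (logged). These conventions are package decisions;
alternatives (e.g. weighted pathways) would shift Ln/Ls by at most a few
percent on realistic data.

## Diversity statistics

For sample size n, a₁ = Σ_{i<n} 1/i and b₁ = Σ_{i<n} 1/i²:

* θ_W = S/(a₁L) per bp; π uses the per-site unbiased factor n_s/(n_s−1)
  with per-site sample sizes under the 70% rule.
* Tajima's D uses the 1989 variance coefficients evaluated at the locus's
  **modal** per-site sample size (missing data make n vary by site; the
  modal n is the least-distorting single choice and is exact on simulated
  data, which have no missing calls).
* From the oriented spectrum ξ_i: θ_H = Σ 2ξ_i i²/(n(n−1)),
  θ_L = Σ iξ_i/(n−1), H = π − θ_H = 2(π − θ_L), and
  Z = (π − θ_L)/√Var with the standardized-H variance
  Var = θ(n−2)/(6(n−1)) + θ²·[18n²(3n+2)b_{n+1} − (88n³+9n²−13n+6)]/(9n(n−1)²),
  θ estimated by Watterson's estimator and θ² by S(S−1)/(a₁²+b₁). Z (and
  the π entering it) is computed on oriented sites only, for comparability
  with the simulated null, which is fully oriented by construction. Sites
  whose sample size differs from the modal n have their derived counts
  rescaled proportionally into the modal-n spectrum — an approximation that
  vanishes without missing data.
* Hudson-style F_ST = 1 − Hw/Hb with Hw the unweighted mean of the two
  within-group mean pairwise differences and Hb the between-group mean.
  Note the finite-sample asymmetry: Hw is per-group unbiased while Hb has
  no n/(n−1) correction, so identical groups give a small negative value of
  order 1/n rather than exactly 0.
* Weir & Cockerham's F_ST uses the haploid variance-components form; the
  multi-site value is the ratio of summed components Σa/Σ(a+b).
* Hudson's ρ: the 1987 moment estimator equating the observed variance of
  pairwise difference counts to θ̂ + θ̂²·g(C), where θ̂ is the mean pairwise
  difference and g(C) averages the two-site pairwise coalescence-time
  covariance (z+18)/(z²+13z+18) over a locus of total scaled rate C. The
  root is found by bisection; estimates are truncated at 0 and capped at
  10⁴ when the observed variance is at or below the free-recombination
  limit. This is the pair-approximation form of the estimator; it is
  reported per locus (the strict site mask is required).

## Coalescent engine

Time is in coalescent units (pairwise coalescence rate 1 at sampling time;
haploid scaling — absolute population size never appears). Exponential
growth at rate g means N(t) = N₀e^{−gt} backward in time, so with k lineages
the waiting time solves C(k,2)·(e^{g(t+w)} − e^{gt})/g = E, E ~ Exp(1),
inverted in closed form via log1p for numerical safety. Mutations follow
the infinite-sites model: S ~ Poisson(θ_L·T_total/2) placed uniformly on
branches. Misorientation flips each segregating site's derived count i to
n−i independently with probability p_mis.

Two implementations share this model: an explicit-tree simulator (used where
haplotypes are needed and in tests) and a vectorized batch engine that
tracks only how many tips each ancestral lineage subtends. Because a
lineage's subtended-tip count is constant over its lifetime, per-frequency-
class branch lengths accumulate from the lifetimes of the two lineages dying
at each merge, making the batch engine O(reps × n) per locus; it accepts
per-replicate (θ, g) vectors, which is what lets the per-locus null
integrate over the ABC posterior cheaply. Both engines are validated
against analytic moments (E[TMRCA], E[T_total], E[S] = θ_L a₁, E[ξ_i] = θ_L/i)
and against msprime at matched scaling (ploidy 1, N = 1, μ = θ_L/2).

The null simulations use no intra-locus recombination. Simulated loci
therefore have somewhat higher variance in (D, Z) than recombining real
loci; the test inherits a corresponding conservatism on strongly recombining
loci.

## ABC fit of the growth model

Each group is fitted independently. Summaries are the counts of SNPs in the
four folded-MAF bins (0, .125], (.125, .25], (.25, .375], (.375, .5],
pooled over the group's control loci (each SNP counts once) and **divided by
the group's total analysed sites**. Normalizing by sites rather than by
SNPs matters: conditional-on-SNP frequencies are scale-free and cannot
identify θ, whereas per-site frequencies sum to the SNP density S/L and
jointly constrain θ and g. The per-SNP variant remains available for
spectrum-shape comparisons.

The reference table simulates the group's exact per-locus (n, L) layout at
parameters drawn from uniform priors — θ ∈ (10⁻⁴, 3×10⁻²) per bp,
g ∈ (0, 200), both configurable; the defaults bracket the diversity of
selfing plant surveys and expansion rates from mild to star-like. The
nearest `tolerance` fraction (default 10⁻³) of draws in Euclidean distance
on MC-standardized summaries is accepted. Accepted parameters are mapped to
ℝ by the tangent bijection u = tan(π((x−a)/(b−a) − ½)) of their prior
interval — so regression-adjusted draws can never leave the prior support —
adjusted by weighted local-linear regression (Epanechnikov weights; the
fourth summary is dropped from the design, being an exact linear combination
of the others), back-transformed, and binned with equal weights on a 72 × 72
grid over the prior rectangle. When the accepted draws have (near-)zero
summary variance — exact-match ties on very sparse data — the adjustment is
skipped and the rejection posterior is used, with a log message. Posterior
draws for downstream simulation use bin midpoints; at 72 × 72 resolution
within-bin jitter changes nothing measurable.

Desk-scale default is 10⁵ simulations per group; `--full-scale` restores
10⁷ (and 10⁶ per-locus null replicates).

## Joint (D, Z) test

Per locus and group: 10⁴ (desk) to 10⁶ null replicates simulate the locus at
its own n and L, with (θ, g) sampled from the group's posterior and
misorientation at p_mis (default 0.00936, a control-locus estimate taken as
a config input). Replicates with S = 0 are excluded from the binned null
but reported (`n_valid`). Valid (D, Z) pairs are binned on a 24 × 24 grid
(576 bins) spanning the central 99.9% of replicate values per axis with
open-ended outer bins. The p-value of an observation is the density-ordered
tail — the total mass of all bins no more probable than the observed bin —
floored at 1/n_valid; an empty observed bin reports the floor. A
one-sided-per-axis alternative is exposed (`method="axis"`).

The reported p-value is discrete (at most 576 support points, with heavy
ties and a lump at 1 from the modal bin). Calibration experiments therefore
assess uniformity on the *randomized* p-value, drawn uniformly within each
observation's density-ordered probability interval (`dz_pvalue_interval`):
this variate is exactly Uniform(0,1) precisely when the binned test is
calibrated, while a continuous-uniform KS test applied to the raw discrete
p-values would reject for discreteness alone. Reported results always use
the deterministic definition.

Misorientation shifts the null's Z downward (flipped low-frequency derived
alleles masquerade as high-frequency ones), which is what guards against
false positives at misoriented loci. Loci whose θ_W exceeds the 95th
percentile of the group's control loci get a `high_theta` warning: Z is
sensitive to mutation-rate variation and deep genealogies, and extreme-θ
outliers should not be over-interpreted.

## Poisson MK models

Gene i in category c (1 control, 2 flowering, 3 symbiotic) contributes
independent Poisson counts with means E[Ps] = θᵢLs, E[Pn] = f_c θᵢLn,
E[Ds] = dᵢLs, E[Dn] = f_c dᵢLn/(1−α_c). The per-gene nuisances (θᵢ, dᵢ)
have closed-form conditional MLEs and are profiled analytically, leaving at
most six structural parameters, optimized by L-BFGS-B with bounds
f ∈ (0, 1], α ∈ (−5, 1) and warm starts from each model's nested parent —
which also enforces the nesting inequalities logL(M0) ≤ logL(M1) ≤ logL(M3)
≤ logL(M4) ≤ logL(M5) and logL(M1) ≤ logL(M2) ≤ logL(M5) up to optimizer
tolerance. With a single gene, model M3 is saturated and the MLEs reduce to
f̂ = (Pn/Ps)(Ls/Ln) and α̂ = 1 − DsPn/(DnPs), which the tests verify.

AIC counts the structural parameters plus the 2-per-gene profiled nuisances;
the nuisance term is common to all models, so ΔAIC and the weights are
unaffected by that bookkeeping choice. Akaike weights default to
w ∝ exp(−ΔAIC) — the convention that reproduces the emulated survey's
published weight column — with the textbook exp(−ΔAIC/2) available via a
flag. Model-averaged f and α are the weight-weighted means per category,
with shared parameters broadcast and M0 contributing f = 1, α = 0. Sites
polymorphic in the ingroup are never also counted as divergence.

## Sliding windows

Windows run on alignment coordinates, default 500 bp at 50-bp steps, full
windows only (a locus shorter than the width yields one whole-locus window).
Gap/masked columns count toward the span but not the analysed sites.
Non-synonymous θ_W divides the window's non-synonymous S by the window's
share of non-synonymous site totals (spread evenly over kept coding
columns). Per-group Tajima's D uses each group's modal sample size within
the window; windows without polymorphism report NA.

## Synthetic data

The generator emulates the survey design: groups of 25 and 32 accessions;
37/11/5 control/flowering/symbiotic loci; lengths log-uniform on 287–8897 bp
(reproducing the survey's wide spread, mean ≈ 2300); one outgroup with
Poisson(0.05·L) substitutions from the ancestral sequence; isolated missing
basecalls at rate 0.002 plus ~5% of sequences truncated (exercising the
span filter exactly where Sanger data lose coverage); misorientation
implemented mechanistically by writing the derived allele into the outgroup
at rate p_mis = 0.00936.

Group models default to (θ = 0.0074, g = 4) and (θ = 0.0066, g = 2),
calibrated so the **realized** within-group statistics match the emulated
survey: growth shrinks realized diversity below the sampling-time θ by
measured factors ≈ 0.43 and 0.56, giving θ̂_W ≈ 0.0032/0.0037 per bp and
mean Tajima's D ≈ −0.73/−0.58.

Sweep-like candidates (by default 4 flowering + 1 symbiotic locus) have
their spectra tilted: each segregating site with derived count i moves,
with probability 1 − tilt^{−i/n}, to a uniform draw from the top classes
{⌈0.85n⌉ … n−1}. This depletes intermediate frequencies while leaving
singletons mostly in place, producing the joint negative-D/negative-Z
signature of hitch-hiking without a mechanistic sweep model; tilt = 1 is the
identity. Tilted sites get freshly drawn carrier sets, so linkage structure
is not preserved at those sites — the stand-in targets the frequency
spectrum only.

What the synthetic experiments show: that every stage recovers what this
generator plants (filters, orientation, spectra, MK counts, posterior
coverage, sweep detection). What they do not show: robustness to features
the generator omits — shared ancestry and gene flow between groups (groups
are independent populations, so whole-sample statistics are more extreme
than within groups), intra-locus recombination, mutation-rate heterogeneity
beyond locus length, alignment errors, and genuine hitch-hiking linkage
patterns.

## Problem sizes and determinism

Desk-scale defaults — 10⁵ ABC simulations, 10⁴ null replicates per locus,
500-locus calibration experiments, 50-repetition coverage experiments, 500
genes for MK recovery (at survey-like count rates of roughly 5 synonymous
polymorphisms and 12 synonymous divergences per gene; much sparser counts
re-introduce the incidental-parameter bias of per-gene nuisance profiling
and visibly depress α̂) — were chosen to give Monte Carlo standard errors
comfortably inside every tolerance asserted by the tests while keeping a
full validation pass in minutes on one core; `--full-scale` restores the
original 10⁷/10⁶ scales. All randomness flows from a single integer seed
through numpy `SeedSequence` substreams; reruns with the same seed and
config are byte-identical.

## Known limitations

* The (D, Z) test is mildly liberal on data with strong missing-data
  structure (the observed statistics come from masked alignments while the
  null is simulated complete), and conservative on strongly recombining
  loci; both effects are visible as a slightly L-shaped control p-value
  distribution in full synthetic-study runs.
* α estimates are noisy at realistic gene counts; the model-averaged values
  are the robust summary, and single-category α (M5) can sit at a bound.
* Hudson's ρ uses the pair-approximation variance expectation; its absolute
  scale should be read as an order of magnitude. On synthetic whole-sample
  data the estimate is further inflated (often to the cap) because the two
  groups are generated as independent populations: cross-group pairwise
  differences behave like sums of two unlinked halves, mimicking free
  recombination. Within-group ρ is the meaningful synthetic quantity.
* The modal-n convention for D and Z under missing data is an approximation;
  loci dominated by off-modal sites deserve caution.
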