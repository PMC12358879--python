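# Methods

This note documents the statistical models implemented in `adslkit`,
the choices made where a design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Competitive water access and the shuffled-label null

The unit of observation is a visit event `(cage, day, timestamp,
animal, corner, licks)`. A visit is *eligible* on a day if its
timestamp is at or after the water-onset time and its corner is
rewarded. The competition statistic for a cage-day is the share of the
`K` earliest eligible visits made by `hAdsl` animals; days with fewer
than `K` eligible visits are retained with the actual count recorded
(`n_counted`), and days with none are flagged undefined rather than
dropped. Timestamp ties are broken by animal id, lexicographically, so
runs are deterministic. Sexes are analyzed separately throughout,
since the phenotype of interest is sex-specific; the pipeline stage
simply loops over sexes.

The null hypothesis is that genotype labels are exchangeable among the
animals of a cage. A null replicate therefore permutes genotype labels
among animals *within* each cage (label counts per cage preserved) and
leaves the visit streams untouched, preserving all temporal and
individual structure. The day-level test statistic is the mean over
cages of the cage's proportion. The two-tailed p-value is

    p = (1 + #{b : |T_b − μ₀| ≥ |T_obs − μ₀|}) / (B + 1)

with the add-one correction so `p ≥ 1/(B+1)`. The center μ₀ is the
*exact* permutation-null mean, available in closed form: a uniformly
random k-subset of a cage's counted visits has expected `hAdsl` share
`k/n` whatever the per-animal visit counts, so μ₀ is the mean over
contributing cages of each cage's `hAdsl` label fraction. Using the
exact center instead of the Monte-Carlo estimate keeps the tie classes
of the discrete null stable; distances are compared with a `1e-9`
absolute tolerance so mathematically tied values stay tied in floating
point. Ties count as extreme (the conservative convention), which
makes the realized type-I error sit slightly below the nominal level —
the calibration suite allows [0.03, 0.07] at α = 0.05 for this reason.
Bonferroni adjustment uses `m` = number of days tested by default;
`m` is always settable and recorded in the report.

Cages containing only one genotype cannot contribute and are excluded
with a warning. The unrewarded-corner control uses the same machinery
with the statistic "difference of per-animal mean visit counts", whose
exact null center is likewise computed in closed form. Tube-test
matches are summarized by the exact two-sided binomial test against
1/2 (point-mass summation).

The visit-ratio operation reports the pooled Σ hAdsl / Σ WT count
ratio across cages and days by default; a per-day mode is provided
because pooling before or after forming the ratio is a genuine
reporting choice and both are defensible.

## Synthetic visit streams

Each animal's first visit after water onset arrives after an
exponential latency with rate λ·θ for `hAdsl` animals and λ for `WT`;
subsequent visits follow a homogeneous Poisson process at the same
rate until the session ends, with corners drawn independently from
fixed choice weights. θ = 1 encodes the exchangeable null; θ > 1 makes
humanized animals systematically faster. Defaults: λ = 6 visits/hour,
3-hour session, 9 days, 5 + 5 animals per cage — the final, most
restricted phase of the water-competition design. The exponential race
gives closed-form checks (a 1-vs-1 race at multiplier θ is won by the
faster animal with probability θ/(θ+1)); θ is a pure synthetic
construct, not an estimate of any biological quantity. The model
deliberately omits circadian structure, learning across days, social
following and lick microstructure, so passing tests demonstrate the
statistics' correctness and calibration, not fidelity to real mouse
dynamics.

## Metabolite tables and group comparisons

Upper-quartile normalization divides each sample's peak areas by that
sample's 75th percentile of *positive* areas and multiplies by the
geometric mean of all samples' quartiles, keeping values in peak-area
units; after normalization every sample's upper quartile is equal, so
the operation is idempotent. The percentile uses linear interpolation
between order statistics (the numpy `linear` method) — percentile
dialects differ silently across ecosystems, so this is fixed and
documented. Normalization is global across samples by default, with a
per-tissue option, since the original normalization scope is a
reporting choice.

Group comparisons are classical pooled-variance Student two-sample
t-tests (an unequal-variance Welch flag is provided but off by
default, matching the named method), two-sided, with 95% confidence
intervals of each group mean from the t distribution with n−1 degrees
of freedom, and the fold change defined as the ratio of arithmetic
group means (hAdsl/WT). Strata with fewer than two samples in either
group are flagged, not dropped. When both groups are constant and
equal, p = 1 by convention. No multiple-testing correction is applied
to the primary p-values; a Benjamini–Hochberg column is appended as
clearly supplementary output. Expression–metabolite correlations are
Pearson's R with the t-transform p-value, computed on raw and
optionally log fold changes (both are reported by the pipeline since
the transform choice is open); constant inputs yield a flagged
undefined result.

The simulator draws peak areas as baseline × fold^(genotype) ×
sampleScale × exp(N(0, σ²)) with log-uniform per-sample scale factors
(default range 0.5–2) recorded in the metadata for tests, and 18
unaffected background metabolites spanning an order of magnitude of
baselines so the per-sample upper quartile is dominated by unaffected
signals — the property that makes the normalization meaningful. With
target metabolites among only a handful of columns the quartile would
absorb part of the planted effect; the slight (~5%) downward pull on
recovered folds visible at default settings is this same mechanism at
benign scale.

## Haplotype statistics

Haplotypes are binary matrices (rows = phased haplotypes, columns =
biallelic SNVs, 1-based strictly increasing positions). VCF input
keeps biallelic SNVs only; multiallelic and non-SNV records are
dropped with a logged count, sites with any missing allele are dropped
entirely (the D formulas assume complete data), and any unphased
genotype is an error. ALT is treated as derived unless an
ancestral-allele annotation is supplied; Tajima's D is invariant to
folding, but carrier and frequency reports need a stated polarity.

π is the mean pairwise difference count, computed from per-site
derived counts as Σ 2c(n−c)/(n(n−1)); S counts polymorphic columns.
Tajima's D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
(a₁ = Σ 1/i, a₂ = Σ 1/i², b₁ = (n+1)/(3(n−1)), b₂ =
2(n²+n+3)/(9n(n−1)), c₁ = b₁ − 1/a₁, c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁²,
e₁ = c₁/a₁, e₂ = c₂/(a₁²+a₂)). D is declared undefined for S = 0 or
n < 4 — the variance constants are ill-behaved at tiny sample sizes —
and scans report such windows rather than dropping them.

Sliding windows tile [first site, last site] with defaults of
10,000 bp windows at 2,000 bp steps (the region of interest spans
roughly 10 kb; the original scan geometry is not known, so these are
package defaults, configurable and recorded). Windows are reported
1-based inclusive (VCF convention) while internal arithmetic is
half-open, converted at the boundary.

Carrier frequency is the Hardy–Weinberg share of individuals with at
least one copy, 1 − (1−p)². The population-scaled selection
coefficient is α = 2·Nₑ·s — the convention is pinned by internal
consistency of the printed conversions (36 = 2 × 10,000 × 0.0018),
which also fixes the default Nₑ = 10,000; the report labels the
convention and both are always settable. The empirical-null operation
retains control variants within δ of the focal allele frequency and
ranks the focal statistic among them with the add-one rule,
directionally ("greater" or "less" — the sidedness of the original
comparison is not knowable, so it is a parameter, not a guess).

## Wright–Fisher model

Diploid, constant size N, non-overlapping generations, genic selection
with genotype fitnesses 1, 1+s, 1+2s. The deterministic
post-selection frequency is the marginal-fitness update

    p' = p (1 + s(1 + p)) / (1 + 2sp)

(allele marginal fitness 1 + s(1+p), mean fitness 1 + 2sp), and the
next generation's count is Binomial(2N, p'); 0 and 1 are absorbing.
This update is frozen here so the stochastic test against Kimura's
diffusion fixation probability u(p₀) = (1 − e^(−4Nsp₀))/(1 − e^(−4Ns))
is well-defined; the simulated fixation rate of a new mutant
(p₀ = 1/2N) agrees with the closed form within Monte-Carlo error.

The haplotype-panel simulator runs this model forward over all 2N
haplotypes with infinite-sites mutation at rate μ per bp per
generation, representing haplotypes as nodes in a mutation tree
(child = parent + one mutation) so generations copy integers, not
sequences. Panels sample n haplotypes without replacement and keep
sites segregating in the sample, assigning distinct uniform positions.
Neutral default conditions: N = 100, n = 50, L = 20 kb, μ = 5×10⁻⁶,
T = 1,200 generations (12N, comfortably beyond the sample's expected
time to common ancestry from a monomorphic start). Sweeps inject a
single selected mutant late enough that a successful sweep is near
fixation at sampling (T − (2/s)ln(2N) − 4/s by default) and condition
on survival — optionally on a minimum sampled frequency — by rejection
sampling that restarts the post-injection phase from a saved snapshot.
Sweep test conditions use 2Ns = 25 (N = 250, s = 0.05) for the paired
sweep-vs-neutral contrast and 2Ns = 50 (N = 1,000, s = 0.025,
n = 100) for the "windowed D below −2" demonstration; at 2Ns ≈ 10 the
sweep is too drift-dominated to separate cleanly from neutrality,
which is itself an instructive property of the statistic.

Recombination is deliberately omitted: the tests need the
site-frequency-spectrum distortion, not linkage maps. Two consequences
are documented as limitations. First, a no-recombination region shares
one genealogy, so window-to-window variation in D carries no
positional information — the sweep cannot be *localized* within a
simulated region, only contrasted against paired neutral panels or
across regions. Second, single-genealogy panels make the neutral
sampling distribution of D wide and slightly left-skewed; the mean
over 200 neutral replicate panels sits near −0.1, consistent with
coalescent (msprime) panels at matched parameters, and well within the
[−0.3, 0.3] acceptance band. A fast alternative generator draws site
frequencies directly from the standard neutral spectrum
(P(count = i) ∝ 1/i); it matches the expected SFS but has no shared
genealogy and is labeled a fixture, never a Wright–Fisher substitute.

## Determinism and numerics

Every stochastic function is a pure function of its parameters and a
seed (integers or numpy Generators accepted); equal seeds give
identical outputs, and pipeline reports are byte-identical across
reruns. Reports are delimited text with documented schemas; a
`run_log.yaml` records the package version, seed and all parameters.
Tie-breaks (timestamps by animal id, permutation distances by the
1e-9 tolerance) are fixed. The acceptance script sizes its
recomputations as: 1,000 calibration replicates at B = 500; 200
neutral panels; 100 paired sweep panels; 200 metabolite tables; 20,000
fixation replicates — sizes chosen to put Monte-Carlo error well
inside each check's tolerance.

## Known limitations

* The behavioral generator is a latency race, not a cognitive model;
  power numbers transfer to real data only insofar as genotype effects
  act like rate multipliers.
* Upper-quartile normalization assumes most metabolites are unaffected
  by genotype; with few measured metabolites or broad effects it
  absorbs signal.
* The Wright–Fisher simulator has no recombination, demography, or
  overlapping generations; sweep localization within a region is out
  of reach by design.
* Tajima's D windows near region edges contain fewer sites and are
  noisier; the scan reports them with their S rather than masking.
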