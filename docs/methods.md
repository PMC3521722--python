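# Methods

## Model

`serialabc` infers piecewise-constant effective-population-size
(*N<sub>e</sub>*) histories from diploid microsatellite genotypes sampled
at two or more time points. The generative model is a serial Kingman
coalescent: gene copies enter the genealogy at their sample's generation
offset (generations before the most recent sample, gbp); while *k*
lineages are active, pairwise coalescences arrive at rate
*k*(*k*−1)/(4*N*(*t*)) per generation, with *N*(*t*) a right-continuous
step function of gbp. Waiting times are exponential within an epoch and
censored at epoch boundaries and sample-entry times, which makes the
continuous-time process exact for piecewise-constant *N* (no
discretization error; the continuous-time approximation itself assumes
sample size ≪ *N*, which holds for realistic draws — a discrete-generation
Wright–Fisher reference implementation exists in the test suite as a
cross-check).

Mutations follow the generalized stepwise model (GSM): counts per branch
are Poisson(μ<sub>ℓ</sub> × length); each mutation moves the repeat count
by ±*s* with *s* ≥ 1 geometric with parameter *P* (*P* = 0 reduces to the
strict single-step SMM), direction symmetric; allele states are reflected
at the boundaries of a window of 40 contiguous repeat counts centred on
the founder allele (configurable). The bounded window follows the
convention of microsatellite simulators in this software family; the
multi-repeat geometric component plays the role that an infinite-allele
admixture plays in other GSM parameterizations. Per-locus rates
μ<sub>ℓ</sub> are either Gamma-distributed around a mean rate μ̄ (shape 2
by default) or shared exactly ("same mean" mode). Diploids are formed by
random pairing of gene copies within each temporal sample (random union
of gametes; the copies are exchangeable, so pairing carries no
information).

## Scenarios and priors

Four competing templates: constant (*N*), increasing
(*N*<sub>anc</sub> < *N*<sub>cur</sub>, change at *t*), bottleneck
(*N*<sub>post</sub> < *N*<sub>pre</sub>, change at *t*) and fluctuating
(*N*<sub>anc</sub> → *N*<sub>hist</sub> → *N*<sub>pres</sub> with
*N*<sub>hist</sub> larger than both and *t*<sub>1</sub> > *t*<sub>2</sub>;
only the expansion-then-decline order is implemented — decline-then-recovery
variants would be configuration extensions). Defaults: *N* uniform on
[10, 10<sup>5</sup>] diploids, event times uniform integers on [1, 5000]
generations, μ̄ uniform on [10<sup>−4</sup>, 10<sup>−3</sup>] per locus per
generation, GSM *P* uniform on [0.1, 0.3]. These ranges reproduce the
shape of the original study design (whose exact per-population prior
table is unpublished) and are configurable per run. Ordering constraints
are enforced by resampling until acceptance, which preserves the uniform
marginals conditioned on the constraint; acceptance failure after 10⁵
attempts raises an error rather than silently reweighting.

Calendar dates carry month resolution and convert to offsets as
round(24 × fractional years before the newest sample). Note that exact
calendar arithmetic does not always match round "approximately *x* gbp"
prose figures quoted for intervention onsets (e.g. an April 2004 onset is
144 gbp from an April 2010 sample, commonly rounded to "≈150"); the
package always reports the exact arithmetic.

## Summary statistics

Per temporal sample, locus means of: unbiased expected heterozygosity
*H<sub>E</sub>* = *n*/(*n*−1)(1−Σp²), allele count, unbiased allele-size
variance, and the Garza–Williamson *M* = (allele count)/(size range + 1);
between the earliest and latest samples, multi-locus Weir–Cockerham θ
(ratio of sums over alleles and loci, gene copies as the sampling unit).
The original analysis used its software's default panel without listing
it; this set was chosen to be sensitive to both the richness-vs-
heterozygosity imbalance of a bottleneck (through *M* and allele counts)
and to temporal drift (through θ). Monomorphic loci are included with
*H* = 0, one allele, zero variance, *M* = 1 so that the summary map is
total on simulated data; missing genotypes are excluded locus by locus.
Shared-allele distance and (δμ)² are deliberately not in the default
panel (configurable extension point, default off).

Descriptive trend tables additionally report rarefied allelic richness
(exact hypergeometric rarefaction, standardized to the smallest per-locus
copy count across time points), the effective allele number 1/Σp², and
two-sided paired t-tests across loci between the earliest and each later
time point. Degenerate t-tests are made total: all-zero differences give
*P* = 1; zero variance with nonzero mean gives *P* = 0 with a warning.

## ABC procedure

Reference tables hold equal simulation counts per scenario (10⁴ per
scenario at desk scale; the original analysis used 10⁶ — larger tables are
a configuration change, not a code change). Summaries are normalized by
their median absolute deviation over the whole table (fallback SD, then 1,
with a warning) and compared by Euclidean distance; the closest 1%
(configurable) are retained, ties broken by row index. Scenario posterior
probabilities come from a weighted multinomial logistic regression of the
scenario label on the normalized summary deviations over the retained
rows, evaluated at deviation zero (Epanechnikov weights in distance; ridge
penalty 10⁻⁶ for numerical stability; the raw retained proportions are
always reported alongside, and are the fallback when the regression is
degenerate or fails to converge). The winning scenario is the highest
posterior probability, exact ties going to the scenario with fewer
parameters.

Parameter posteriors use local-linear (Beaumont-type) adjustment within
the chosen scenario's simulations: rejection is re-run among that
scenario's rows (so the retained count is independent of how the other
scenarios fit), parameters are logit-transformed over their prior bounds,
regressed on the summary deviations with Epanechnikov weights,
residual-corrected to deviation zero and back-transformed — guaranteeing
adjusted draws stay inside the prior bounds. Weighted medians and
0.025/0.975 quantiles use a weighted empirical CDF whose positions reduce
to type-7 linear interpolation under uniform weights. A parameter whose
95% interval covers more than 90% of its prior range is flagged "not
estimable" (a posterior flat across the prior), mirroring how a flat
timing posterior is reported rather than over-read. Percent change in
*N<sub>e</sub>* is reported as trunc(100(1−after/before)) for declines and
trunc(100·after/before) for increases — the convention consistent with the
published tables this layout mirrors (two printed rows in those tables are
internally inconsistent with their own medians and are not reproducible
under any single convention).

Scenario-choice confidence: pseudo-observed datasets (PODs) are simulated
from each scenario's prior and classified against the already-built
reference table (nothing held out; with thousands of rows per scenario the
chance a POD's near-duplicate drives its own classification is
negligible). Type I error per scenario is the fraction of its own PODs it
fails to win; type II is reported both pooled (fraction of other
scenarios' PODs assigned to it, the primary definition) and conditional
(among datasets assigned to it, the fraction whose truth was different).

## Synthetic data

`serialabc.synthetic` ships templates for the seven intervention
populations and two negative controls of the motivating study design:
11–17 loci, 2–4 temporal samples of 32–119 diploids collected 2002–2010,
24 generations per year, with the published posterior medians as the
ground-truth demographic parameters (the one non-estimable event time uses
a synthetic mid-prior stand-in, marked in the template docstring). Truth
records serialize to JSON alongside the GenePop export, so recovery can be
scored end to end. Defaults for what the study never fixed: μ̄ = 5×10⁻⁴
(mid prior), Gamma shape 2 across loci, GSM *P* = 0.2, founder allele 30
repeats. The generator emulates the study's sampling design and mutation
process only: no genotyping noise (null alleles, allelic dropout — the
real data were pre-filtered for these), no population structure or
migration, no seasonal census fluctuation. Passing tests therefore show
the inference machinery recovers truths generated by its own model class
at study-like sample sizes; they cannot show robustness to model
misspecification in field data.

## What the checks do and do not show

The simulator is validated against closed forms (pair TMRCA 2*N*, total
branch length 4*N*Σ1/*i*, Ohta–Kimura equilibrium heterozygosity
1−(1+8*N*μ)<sup>−1/2</sup>), against msprime on a two-epoch serial design,
and against a discrete Wright–Fisher reference. The ABC stack is validated
on analytically tractable toys (full retention returns the prior; the
conjugate-Gaussian toy matches the closed-form posterior within 10% at
10⁵ simulations; rejection equals a brute-force distance sort).

The end-to-end recovery experiment uses the strong-bottleneck island
template (89+68 diploids, 13 loci, 1090 → 261 at 61 gbp) and a
constant-truth negative control on the two-sample control design: at 10⁴
simulations per scenario the bottleneck is chosen in ≈95–100% of seeds,
the true post-decline *N<sub>e</sub>* falls inside the reported 95%
interval in ≈80–95%, and the negative control avoids the decline scenarios
in ≈76–90% (binomial noise at 20–25 seeds spans these ranges). The
parameter-recovery property prescribed at a larger design (3×100 diploids,
30 loci, 2×10⁴ rows/scenario) is exercised at this template scale — the
posterior-median-within-factor-3 and coverage assertions are part of the
same experiment.

Known limitation, documented deliberately: mild *and* recent bottlenecks
whose pre-decline epoch is still visible in the oldest samples (e.g. a
13 200 → 1 900 decline at 88 gbp sampled from 78 gbp onward) are
frequently attributed to the *fluctuating* scenario instead — that
scenario nests bottleneck-like trajectories, and with locus-averaged
summaries the two are close to likelihood-equivalent there. The direct
(retained-proportion) estimates show the same ambiguity, so this is a
property of the scenario geometry at these sample sizes, not of the
logistic step; the original study's per-population prior customizations
(unpublished) presumably sharpened this contrast. Type I error of
scenario choice is correspondingly large on the four-scenario design
(tens of percent) while pooled type II stays several-fold smaller — the
same qualitative ordering the motivating study reported.

## Numerical and reproducibility choices

Coalescent and mutation kernels are numba-compiled; one
`numpy.random.Generator` drives a run, per-locus kernel seeds are drawn
from it (so the fast summary path and the full genotype export consume
identical randomness and yield identical statistics), and every CLI output
directory receives the exact configuration and seed. Distances use stable
sorts so ties are reproducible; the logistic and local-linear regressions
are deterministic given the retained set. Desk-scale problem sizes (10⁴
rows per scenario, 20–25 recovery seeds, 25–40 PODs per scenario) keep a
full synthetic end-to-end run in minutes on one CPU and are stated in the
scripts that use them.
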