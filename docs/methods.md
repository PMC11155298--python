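# Methods

This note documents the statistical models, conventions and numerical
choices behind `toxpod`, and what the synthetic-data generator does and
does not emulate.

## Dose designs

A design is a vehicle control (dose exactly 0; no solvent modeling) plus a
geometric half-log series: positive doses descend from the top dose by √10,
so adjacent log10 doses differ by exactly 0.5 before any rounding. Doses are
stored unrounded; the 3-significant-figure style (0.316, 3.16, 31.6 …) is
applied only to labels and sample ids. The default study layout used across
examples, tests and the acceptance script is 9 positive doses from 1000 µM
with 4 biological replicates — the common shape of in-vitro
concentration-response transcriptomics designs.

## Synthetic data generator

The generator emulates the *statistical substrate* of a concentration-
response RNA-seq experiment, not the reads:

* **Counts.** Feature i in sample j is negative-binomial with mean
  `sf_j · 2^(μ_i(dose_j))` and variance `m + α·m²` (dispersion α = 0.05 by
  default, a typical bulk-RNA-seq value; library size factors default to 1,
  with optional log-normal jitter to exercise normalization). Mean curves
  μ_i are drawn from the same families the engine fits (hill, linear,
  saturating exponential, power) with top-of-range effects of 1–3 log2
  units, or are flat for null features.
* **Ground truth.** Each responsive feature records `true_bmd`: the dose
  where the noiseless mean departs from the control mean by the generating
  residual SD (0.25 log2 units by default), found by bracketing + Brent
  root-finding on the curve itself — deliberately independent of the fitting
  engine, and consistent with the engine's one-SD benchmark response.
* **Splicing events.** Per sample, total junction reads are Poisson at the
  event's expected depth (default 100) and inclusion reads are binomial with
  probability PSI(dose)/100. ΔPSI trajectories are saturating (Hill-shaped)
  with amplitudes of 10–40 percentage points for responsive events;
  trajectories are clipped to [0, 100] with a logged warning. Event types
  default to the empirical mix where intron retention and exon skipping
  dominate.
* **Study scenario.** `simulate_study` encodes the qualitative structure the
  pipeline is designed to detect: gene-expression half-max doses sit in the
  upper dose range while intron-count and splicing-event half-max doses sit
  low, so splicing responds at doses where DEG counts are still zero and
  intron-derived pathway BMDs undercut expression-derived ones. Gene sets
  are synthetic: a block of "perturbed pathway" sets drawing ~70% of members
  from responsive genes over a background of random sets. Intron features
  attach to responsive genes so both modalities can hit the same sets.

Not emulated: alignment artifacts, batch effects, GC/length biases,
cytotoxic RNA degradation, junction discovery, or a real GO hierarchy.
Passing tests therefore demonstrate correctness of the statistical machinery
under its stated model, not robustness to real-data artifacts.

## Preprocessing and differential expression

Counts are transformed to log2(count+1) and each sample is shifted so its
median equals the grand median of sample medians (idempotent; skipped with a
warning for single-feature matrices). Features with a summed count below 10
across all samples are dropped first — the total-across-samples reading of a
low-count rule, the simplest reproducible interpretation.

The DEG caller is a per-dose-vs-control Welch t-test on normalized log2
values with Benjamini–Hochberg correction across features within each
contrast; a DEG requires FDR < 0.05 **and** linear |fold change| > 1.5. This
is an explicit stand-in for a negative-binomial GLM: the package's focus is
downstream of the DE caller, and a self-contained test on the normalized
scale keeps the pipeline dependency-free and distribution-honest. Degenerate
zero-variance features receive p = 1 when group means agree and p = 0
otherwise (documented convention, also used by the ANOVA prefilter).

The BMD prefilter is a one-way fixed-effects ANOVA across all dose groups
(p ≤ 0.05) combined with a max absolute fold change ≥ 1.5 of any positive
dose versus control, computed on group means in log2 space and
back-transformed (|FC| means max(FC, 1/FC)). Because group differences are
invariant to per-sample median shifts, the prefilter pass set commutes with
normalization.

## Differential splicing

PSI is 100·inc/(inc+exc), reported only when coverage (inc+exc) reaches 10
reads (the default; the threshold is configurable as published analyses
rarely state it). The ΔPSI point estimate is the difference of group means
of per-replicate PSI over covered replicates — deliberately decoupled from
the posterior. Each group's posterior is the equal-weight mixture of its
covered replicates' Beta(inc+1, exc+1) posteriors, sampled by first drawing
a replicate uniformly and then from its Beta; the mixture's spread combines
read-sampling noise with the biological spread between replicates, which is
what makes the criterion a genuine robustness filter rather than a pure
coverage test. Monte-Carlo draws (default 10 000) of treated − control give
an equal-tailed central 95% credible interval; MV_ΔPSI is the distance from
zero to the nearer endpoint when the interval excludes zero, else 0. An
event is significant iff |ΔPSI| > 5 points and MV_ΔPSI > 0.

Two design choices deserve note. First, replicate weighting: pooling all
reads within a group (the obvious conjugate alternative) yields a posterior
exactly as wide as the sampling distribution, so the interval criterion
would reject a true null at almost exactly its nominal rate and add nothing
beyond a p-value; the replicate mixture instead inflates with between-
replicate disagreement, keeping the null false-positive rate of the
two-criterion rule well below 5% while leaving moderate planted shifts
(ΔPSI = 30 at depth 200) detected essentially always. Second, the credible
level: a central 95% interval, matching the "95% confidence interval
removes non-confident events" reading; the level is a parameter
(`cred_level`). The Monte-Carlo streams are keyed to each
group's sample set rather than its argument position, so exchanging the
control/treated labels exactly negates ΔPSI draws and preserves MV.

## BMD engine

**Likelihood.** y ~ Normal(f(d; θ), σ²) with a single σ across dose groups
(constant variance on the log2 scale). σ is profiled exactly (σ̂² = RSS/n);
the RSS carries a floor of 1e-24 per observation so noiseless data yield
finite log likelihoods without affecting any realistic fit. AIC counts the
mean parameters plus one variance parameter.

**Model suite.** linear, poly2, poly3, power (a + b·d^p, exponent ≥ 1 by
default to avoid infinite slope at 0; configurable), hill
(v₀ + v·dⁿ/(kⁿ+dⁿ), n ≥ 1 by default), and exp3 — here a 3-parameter
saturating exponential a + b·(1 − e^(−c·d)) on the log2 scale, since the
classical multiplicative exponential parameterizations are not meaningful
for median-centered log2 data. Results are labeled by family so the
parameterization is transparent. Four/five-parameter exponentials are
omitted to keep the suite tractable. Dose enters in µM on the natural
scale (models are functions of dose, not log-dose).

**Fitting.** Polynomials are solved in closed form on doses rescaled to
[0, 1] for conditioning. Nonlinear families use trust-region-reflective
bounded least squares from data-driven starts plus seeded Latin-hypercube
draws over the parameter boxes (10 starts by default; positive-scale
parameters sampled on the log scale). Everything is deterministic given the
seed; in the batch driver each feature's seed derives from the global seed
and a CRC of the feature id, so results do not depend on feature order.

**Selection.** Among converged polynomials, a higher degree is kept only if
the nested likelihood-ratio chi-square (df = parameter difference, threshold
p < 0.05) favors it. The winning polynomial then competes with the
non-polynomial families by lowest AIC (ties broken toward fewer parameters).
If the winner is Hill with k below one third of the lowest positive dose it
is flagged and the lowest-AIC non-Hill model with goodness-of-fit p > 0.05
takes its place; with no such fallback the flagged Hill is returned and the
flag travels with the result.

**Goodness of fit.** Likelihood-ratio lack-of-fit test against the saturated
model (one mean per dose group, common σ): 2·(ℓ_full − ℓ_model) ~ χ² with
df = groups − mean parameters (p = 1 when df ≤ 0). With ~40 observations
this profiled-variance LRT runs somewhat anti-conservative relative to its
nominal level (rejection rates above the nominal 10% on correctly specified
simulations), which makes the fit-p ≥ 0.1 rejection filter strict rather
than lenient; results report the p-value so the behavior is visible.

**BMD.** The adverse direction is the sign of f(max dose) − f(0). The BMD is
the smallest positive dose with |f(d) − f(0)| = σ̂, bracketed on a combined
log/linear grid of 1024 points and refined by Brent's method to ~1e-10
relative tolerance. A curve that never reaches the one-SD departure within
the tested range yields no BMD (`fail_no_bmd`).

**BMDL/BMDU.** Profile likelihood with the BMD pinned through the equality
constraint sign·(f(b) − f(0)) = σ, optimized by SLSQP over (θ, log σ) with
warm starts along the profile. Each bound solves
2·[ℓ̂ − ℓ_profile(b)] = χ²₁(0.90), i.e. one-sided 95% per bound — the
standard convention for benchmark-dose confidence limits. The upward search
is clamped at 10× the top dose; a side on which the profile never reaches
the cutoff is reported as undefined and treated as an infinite BMDU/BMDL
ratio by the filters. Bounds are located by geometric expansion plus Brent
root-finding at 1e-3 relative tolerance (an interval-endpoint precision well
below any downstream use of the bounds).

**Filters.** In rejection order: BMD outside [lowest positive dose, top
dose] (`fail_range` — "lowest" is read as the lowest *positive* tested
dose); goodness-of-fit p < 0.1 (`fail_fit_p`); BMDU/BMDL > 40
(`fail_ratio`). Each result carries its first failing rule.

## Pathways and POD

Gene-level BMD/BMDL/BMDU are medians over a gene's passing features
(identity for single-feature genes; intron feature ids encode their host
gene). The over-representation test is the two-tailed Fisher exact test
(sum of all 2×2 table probabilities not exceeding the observed table's) of
the passing query genes against each set, with the background universe
defaulting to all genes whose features entered the analysis for that
modality (the low-count-filtered matrix); the full GMT universe can be
supplied instead. Significance uses raw p < 0.05 plus at least 5 query
genes in the set — multiplicity-uncorrected by design, mirroring common
benchmark-dose pathway practice; a BH-adjusted column is emitted alongside
for reference.

The POD ranks significant pathways by median BMD ("most sensitive") and
averages median BMDL over the 20 lowest; with fewer than 20 significant
pathways it falls back to the median BMDL over all of them. Because
sensitivity ranking and POD averaging intentionally use different quantities
(BMD vs BMDL), both the top-20 and all-pathway means are reported, and the
top-20 mean provably undercuts the all-pathway mean whenever ranking and
averaging agree. Reporting helpers produce accumulation curves (count of
BMDs at or below each dose), exclusive upset-style overlap counts, paired
expression/intron pathway BMDs (pathway "mean BMD" is the mean over the
pathway's query-gene BMDs) and a pathway–condition edge table for external
network rendering.

## Problem sizes

Simulation-backed checks use: 200 Hill features for recovery/coverage, 2000
null features for prefilter calibration, 1000 null + 200 planted events for
splicing calibration, and a 500-gene / 200-intron / 200-event study for the
full pipeline — sizes chosen so each property is measured with useful
precision while the whole suite stays comfortably runnable on a laptop CPU.

## Known limitations

* The DEG stage is a Welch-t stand-in, not a count GLM; absolute DEG counts
  on real data would differ even though the dose-response machinery is
  unaffected.
* The profiled-variance lack-of-fit test is anti-conservative at small n
  (see above); BMDL coverage is validated empirically instead (≥ 85% at
  nominal one-sided 95% over the study layout).
* Pathway enrichment ignores ontology structure (no term propagation or
  DAG-aware pruning).
* Unbalanced designs and missing samples are not supported; the constant-
  variance assumption is not tested against the data.
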