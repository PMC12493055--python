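# Methods

gxekit implements the three computational arms of a gene-environment
interaction analysis — a two-sample Mendelian-randomization (MR) battery, a
proportional-hazards dose-response arm with a sliding-removal sensitivity
procedure, and a rare-variant loss-of-function (LOF) burden arm — together
with synthetic-data generators that emulate each input class with known
ground truth. This note records the models, the defaults and why they were
chosen, the numerical conventions, and the limits of what the synthetic
studies demonstrate.

## Two-sample MR battery

**Model.** Each instrument j carries an exposure association (b_xj, se_xj)
and an outcome association (b_yj, se_yj) aligned to the same effect allele.
The per-SNP causal estimate is the Wald ratio b_yj/b_xj with first-order
delta-method standard error se_yj/|b_xj| by default (a second-order variant
including the exposure-side term is available behind a flag; with the
instrument-strength filters in place it changes nothing at the reported
precision). Inverse-variance weights are w_j = 1/wald_se_j^2.

**Pipeline order.** Instrument selection (p < 5e-5, strict), greedy
p-value-ranked clumping (r^2 >= 0.001 within 10,000 kb excludes; ties broken
by keeping the smallest p), harmonization (swapped alleles negate b_y;
strand-complement labels resolved for non-palindromic pairs; palindromic
A/T and G/C variants with MAF > 0.42 dropped; incompatible pairs dropped
with a logged count), then radial-MR outlier removal *before any other
statistical test*, then the outcome-vs-exposure p-value pleiotropy filter
(remove iff p_y < p_x, strict), then the estimators and sensitivity
statistics on the surviving set. Every removal is logged with its reason
and the report's counts satisfy final = initial - removals.

**Estimators.**

* IVW: weighted mean of ratios; multiplicative random-effects standard
  error se_fixed * max(1, sqrt(Q/(k-1))) — heterogeneity can widen but never
  narrow the interval; two-sided normal p.
* MR-Egger: instruments oriented so b_x >= 0 (negating b_y in tandem, the
  conventional treatment that makes the intercept identifiable); weighted
  regression of b_y on b_x with intercept, weights 1/se_y^2; the same
  max(1, sqrt(Q/df)) scaling with df = k-2; t p-values on k-2 df. Note that
  the orientation step sign-flips instruments whose *estimated* exposure
  effect is negative, which cancels part of any directional pleiotropy they
  carry; the intercept is therefore interpreted after instrument selection,
  when sign errors are negligible.
* Weighted median: sorted ratios interpolated at cumulative normalized
  weight 0.5 (midpoint convention: the i-th sorted ratio sits at
  (cumsum(w) - w_i/2)/sum(w)); consistent when valid instruments carry a
  weight majority.
* Weighted mode: argmax of a weighted Gaussian kernel density over the
  ratios on a 2048-point grid, bandwidth = factor * 0.9 * min(sd,
  IQR/1.349) * k^(-1/5) (modified Silverman, factor default 1). A zero
  bandwidth (degenerate kernel) is an error; identical ratios short-circuit
  to that ratio.
* Weighted-median/mode standard errors: parametric bootstrap (ratios
  resampled from Normal(ratio_j, wald_se_j), weights fixed, default 1000
  draws, caller-supplied seed). No closed form exists; explicit seeding
  keeps reports reproducible.

**Sensitivity statistics.** Cochran's Q around the IVW estimate with
chi-square(k-1) p; heterogeneity I^2 = max(0, (Q-(k-1))/Q); an
instrument-strength variant I^2_GX computed from exposure-side dispersion
(how far the SNP-exposure effects stand out of their sampling noise) is
exposed separately because the two are routinely conflated in published
tables; mean F = mean((b_x/se_x)^2) with a weak-instrument flag at <= 10;
radial-MR outliers as SNPs whose Q contribution w_j(ratio_j - beta_ivw)^2
exceeds the chi-square(1) critical value at alpha = 0.05, removed in a
single pass (outliers are removed once, up front; iterating to a fixed
point is available as a battery option); leave-one-out IVW per SNP with
the count of
left-out fits at p > 0.05.

## Survival arm

**Cox fitter.** The Efron-tie-corrected partial likelihood is maximized by
damped Newton iteration (step-halving on the objective) to a gradient
max-norm below 1e-8 on an internally standardized covariate scale;
coefficients and Wald standard errors (observed information) are mapped
back to native units. Efron rather than Breslow because questionnaire-
derived doses and coarsened times produce heavy ties. The fitter is
hand-vectorized (suffix cumulative sums over the risk sets, grouped
reduction over tied event times) because the sliding-removal procedure
needs hundreds of refits per cohort; it agrees with lifelines'
`CoxPHFitter` to ~1e-4 relative on tied data (cross-checked in the tests)
and with a grid maximization of the written-out partial likelihood to 1e-4
absolute on small fixtures. Degenerate inputs raise immediately: no events,
no dose variation, or a constant covariate.

Two time scales are supported: age at event and time from enrolment, both
with enrolment age available as a covariate rather than left truncation,
mirroring the "adjusted for age at enrolment" design.

**Hazard-ratio reporting.** `hazard_ratio(fit, term, delta)` =
exp(coef * delta) reports the multiplicative risk for a stated dose
difference in native units (e.g. HR per 100 kJ/min, or per 10,000
MET-min/week). `met_equivalent` converts kJ/min to METs via 1 MET = 1
kcal/kg/h and 4.184 kJ/kcal.

**Quartile contrasts.** Dose quartiles are assigned by rank with stable
ties, so a zero-inflated dose distribution puts the zero mass in Q1; the
Kaplan-Meier contrast of interest is Q2 vs Q4 because Q1 is dominated by
zero recorded activity. Product-limit curves come from lifelines.

**Sliding-removal sensitivity.** Records are ranked by dose descending;
for every contiguous rank window of 20 (step 1, so consecutive windows
overlap by 19), the Cox model is refit on the remaining n-20 records and
the removed subset's mean dose recorded. The reported statistic is the
Pearson correlation (t-transform p) between removed-subset mean dose and
the refit dose coefficient across the n-window+1 windows: if the
association is carried by the heaviest exercisers, removing them weakens
the coefficient and the correlation is negative. Failed window fits are
flagged, logged, and excluded from the correlation rather than aborting
the procedure. Warm-starting each refit from the previous window's
solution keeps the full sweep at well under a second for n = 400.

## Burden arm

**Phenotype classifier.** Weekly hours per activity class are the product
of a frequency category mapped to its lower bound in sessions/week
(none 0, 1/wk 1, 2-3/wk 2, 4-5/wk 4, everyday 7) and a duration band
mapped to its lower bound in hours (<15 min 0 ... >3 h 3). Lower bounds
guarantee strict "more than" semantics; band midpoints are available as an
option. A record is *extreme* iff strenuous hours > 6 or other leisure
exercise hours > 12 (strictly), *sedentary control* iff both are zero,
else *neither*. The summary rule is used rather than an enumerated list of
category combinations because frequency categories are mutually exclusive
and cannot be combined conjunctively.

**Qualifying variants and collapsing.** Qualifying variants are rare
(MAF strictly < 1%) and loss-of-function (nonsense or splice-site). The
burden statistic is the per-gene carrier indicator (>= 1 qualifying
variant), the standard collapsing convention for ultra-rare LOF; a
qualifying-variant count mode is available behind a flag.

**Firth logistic regression.** The gene test maximizes the Jeffreys-
penalized log likelihood l(beta) + 0.5 log det I(beta) by Newton iteration
with the hat-adjusted score U*_r = sum_i (y_i - p_i + h_i(1/2 - p_i)) x_ir,
step-capped and step-halved on the penalized objective, converging at
score max-norm < 1e-6. The penalty keeps estimates finite under the
complete or quasi-separation that rare carriers routinely produce (verified
exhaustively for all separated 2x2 configurations with n <= 12).
Per-coefficient p-values are penalized likelihood-ratio tests — the
coefficient is constrained to zero, the remaining coefficients re-maximized
with the column retained in the penalty, and 2*(pl_full - pl_0) referred to
chi-square(1) — which calibrates better than Wald when carriers are rare.
Genes with zero or constant carrier status are skipped and logged; BH FDR
is applied across tested genes (default threshold 0.05; the stricter 0.01
used for headline gene lists is a flag). Sex-stratified scans filter the
phenotype table on the sex column; no interaction model is fit.

**Overlap and enrichment.** Gene-set overlap builds the 2x2 membership
table within an explicit universe and applies the conditional two-sided
Fisher exact test (p = sum of same-margin tables with point probability <=
observed, via scipy; the sample odds ratio ad/bc uses a Haldane 0.5
correction when a cell is zero, flagged in the log). `enrichment_scan`
repeats the test across annotation sets with BH adjustment.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` and are
byte-reproducible; seeds are explicit arguments and echoed into output
headers. One global seed expands to per-stage sub-seeds by a fixed counter
scheme so stages can be re-run alone.

**Summary statistics.** Per SNP: MAF ~ U(0.05, 0.5); true exposure effect
gamma_j = |N(0, 0.08)| (drawn positive because allele coding is arbitrary
and one-signed effects are what makes "directional" pleiotropy genuinely
directional on the ratio scale); sampling noise follows the standard GWAS
approximation se = 1/sqrt(2 p (1-p) n) with default sample sizes 175,000
(exposure) and 65,000 (outcome), chosen to match the scale of the
motivating exercise and ALS GWAS and yielding mean F in the hundreds for
unselected instruments. The outcome effect is theta * gamma_j + alpha_j +
noise, where alpha_j is zero for valid instruments and, for a configurable
invalid fraction, is drawn N(mean, sd) with mean 0 (balanced) or 0.1
(directional) and sd 0.005 by default. The balanced spread is deliberately
on the scale of the outcome sampling noise: the multiplicative
random-effects model underlying the IVW/Egger standard errors assumes
dispersion proportional to se_y^2, and a balanced null with per-SNP direct
effects many times the sampling noise concentrated in a minority of
instruments produces a heavy-tailed weighted-residual mixture under which
no overdispersion-scaled t-test holds its size. Gross outliers (a
configurable fraction) receive direct effects inflated at least tenfold.
A configurable fraction of variants gets palindromic allele pairs, and
`allele_scramble` randomly swaps outcome allele labels with consistent
beta negation and frequency reflection — harmonization must undo it
exactly. Instruments are generated independent, matching the
post-clumping state; LD enters only through the user-supplied pairwise
map consumed by the clumping step.

**Cohorts.** The activity dose is zero-inflated (default 25% zeros, the
observed dominance of zero recorded activity in the bottom quartile) with
a log-normal body (log-mean log(1000), log-sd 1.0, on a MET-min/week-like
scale). Event times are exponential with hazard
baseline * exp(beta_dose * f(dose)) — a constant baseline so the Cox
coefficient has a closed-form target — with f the identity (linear) or
dose * 1[dose > q-th dose quantile] (threshold; quantile-parameterized so
the model is scale-free across activity units). Censoring is independent
exponential. The discrimination study pairs threshold and linear cohorts
at beta_dose = 6e-4 per MET-min/week (HR 2 per ~1150 MET-min/week among
those affected) and baseline hazard 0.05/person-year (~a third of the
cohort has events): a design sweep showed that with substantially weaker
effects or sparser events the window-coefficient series is dominated by
smoothing noise and the procedure cannot distinguish the two hypotheses
at n = 400.

**Genotypes.** Per gene, carrier status is Bernoulli (default 2%) in
controls; signal genes multiply the case carrier odds by a configured
odds ratio. Each gene has two qualifying variants (nonsense and
splice-site, MAF < 1%) among which carriers are split at random, plus one
common missense variant the LOF filter must discard. Covariates are
standard normal and independent of phenotype (they exist to exercise the
adjusted model, not to confound).

**Gene sets.** Exact requested overlap within a synthetic universe.

## Validation studies and their scales

`gxekit.validation` runs each study at a fixed desk scale chosen to keep
the whole battery a few minutes on one CPU: IVW recovery 500 replicates of
100 SNPs; Egger calibration 1000 replicates (power 200) of 200 SNPs;
weighted-median breakdown 200 replicates with 40% invalid instruments;
radial detection 200 replicates of 50 clean instruments plus one planted
outlier; relabeling invariance 50 random configurations; Cox recovery 200
replicates of n = 1000 (plus 20 small grid-oracle fixtures); sliding
discrimination 100 paired replicates of n = 400 with window 20; burden
calibration and power 50 replicates of 200 genes (1000+1000 and 2000+2000
samples respectively); Fisher enumeration over all 46,376 tables with
total <= 30; BH over 10,000 random 20-vectors. `scripts/acceptance.py`
re-runs exactly these studies from a single seed.

## What the synthetic studies do and do not show

The generators reproduce the *structure* of the real inputs — effect/noise
scales, zero inflation and right skew, rare-carrier sparsity, palindromic
and scrambled alleles — but not their hard parts: there is no LD between
instruments (clumping is exercised only through constructed LD maps), no
assortative mating/population stratification or selection bias behind the
summary statistics, the dose distribution is emulated in shape rather
than derived from a questionnaire scoring rule, hazards are constant over
age, covariates are independent of phenotype, and carriers within a gene
are exchangeable. Passing the validation battery therefore demonstrates
that the estimators, filters and tests implement their definitions
correctly and behave as theory predicts under the stated generative
models — not that any particular epidemiological conclusion transfers to
real biobank data. Headline numbers from access-controlled cohort data are
not reproducible here and are not targeted.

## Known limitations

* No LD-proxy lookup: exposure instruments absent from the outcome GWAS
  are dropped (counted in the log) rather than proxied.
* The sliding-removal correlation targets the refit coefficient; the
  variant correlating removed-subset dose with remaining-subset onset age
  is noted as an alternative reading but not implemented.
* SKAT-O-style variance-component tests are out of scope; the burden
  engine is Firth collapsing regression only.
* `pipeline_cli` formats are deliberately plain TSV/CSV; VCF ingestion is
  an extension point, not a feature.
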