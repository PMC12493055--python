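# gxekit

Toolkit for gene-environment interaction studies of the kind that ask
whether an environmental exposure (here: leisure-time physical exercise)
causally modifies disease risk or onset (here: amyotrophic lateral
sclerosis), and in whom. It bundles the three computational arms such
studies combine, each exercisable end to end on synthetic data with known
ground truth:

1. **Two-sample Mendelian randomization** (`gxekit.mr`) — SNP instruments
   for genetic liability to the exposure from one GWAS, SNP-outcome effects
   from an independent GWAS. Per-SNP Wald ratios beta_Y/beta_X are combined
   by multiplicative random-effects IVW,
   `beta_IVW = sum(w_j r_j)/sum(w_j)`, `se = sqrt(1/sum w_j) * max(1, sqrt(Q/(k-1)))`,
   alongside MR-Egger (slope + directional-pleiotropy intercept), weighted
   median and weighted mode, with the full sensitivity battery: Cochran's
   Q, heterogeneity I^2 and instrument-strength I^2_GX, mean F,
   radial-MR outlier removal, and leave-one-out. Instrument selection,
   greedy LD clumping, allele harmonization with palindrome exclusion and
   an outcome-vs-exposure p-value pleiotropy filter come first, in the
   standard stringent order.
2. **Survival dose-response** (`gxekit.survival`) — Cox proportional
   hazards by damped Newton maximization of the Efron-corrected partial
   likelihood, hazard-ratio reporting for stated dose deltas (e.g. HR per
   100 kJ/min), Kaplan-Meier quartile contrasts, and a sliding-removal
   sensitivity procedure: refit the model with each window of 20
   consecutive dose-ranked participants removed and correlate the removed
   subset's mean dose with the refit coefficient — a negative Pearson r
   means the association is carried by the heaviest exercisers.
3. **Rare-variant LOF burden** (`gxekit.burden`) — an extreme-exercise
   questionnaire classifier (>6 h/week strenuous or >12 h/week other
   leisure exercise), a rare (MAF < 1%) nonsense/splice-site qualifying-
   variant filter, per-gene carrier collapsing, Firth-penalized logistic
   regression (finite under separation; penalized likelihood-ratio
   p-values) with Benjamini-Hochberg FDR, and Fisher-exact gene-set
   overlap/enrichment.

`gxekit.simulate` generates all three input classes with controllable
ground truth (true causal effect, pleiotropy fraction and direction,
palindromic/scrambled alleles, threshold-concentrated hazard effects,
per-gene carrier odds ratios); `gxekit.validation` turns those generators
into parameter-recovery and calibration studies. See `docs/methods.md`
for the models, defaults and their rationale.

## Worked example

Run the whole pipeline on freshly simulated data (a 150-SNP exposure GWAS
with true causal effect theta = 0.1, a 400-participant cohort whose dose
effect is confined above the 90th activity percentile, and an 800-sample
carrier package with one planted odds-ratio-10 gene among 50):

```sh
gxekit all --seed 3 --out-dir demo/
```

Excerpts of what it prints (full tables are written under `demo/`):

```
IVW beta        0.090392
IVW se          0.00662304
IVW P-value     2.07135e-42
Egger-intercept beta    0.00108917
Egger-intercept P-value 0.34079
Mean F test     511.481
IVW Cochran's Q test P-value    0.963218
Radial MR outlier SNPs  7
Total number of SNPs    120
...
sliding-removal Pearson r = -0.6353 (p = 1.85e-44, 0 failed fits)
...
    gene  carriers_cases  carriers_controls  odds_ratio       pvalue          fdr
GENE0001              68                  2   33.504419 5.519705e-20 2.759852e-18
...
overlap = 30, OR = 5.082, p = 1.884e-09
```

Reading the numbers: the IVW estimate 0.090 +/- 0.007 recovers the
simulated causal effect 0.1 (slightly attenuated by instrument selection
and radial trimming, as expected), the null Egger intercept and Q p-value
show no directional pleiotropy or heterogeneity, and mean F >> 10 rules
out weak instruments. The strongly negative sliding-removal correlation
flags that the cohort's dose association is driven by the top exercisers —
exactly the planted threshold effect. The burden scan ranks the planted
gene first with an inflated carrier odds ratio, and the gene-set overlap
test recovers the planted 30-gene overlap.

Each subcommand is also available separately (`simulate`, `mr`,
`survival`, `burden`, `overlap`) on the plain TSV/CSV formats documented
in `gxekit.io`, e.g.

```sh
gxekit mr --exposure s.exposure.tsv --outcome s.outcome.tsv \
    --p-threshold 5e-5 --clump-r2 0.001 --clump-window-kb 10000 \
    --palindrome-maf 0.42 --radial-alpha 0.05 --seed 1 --out mr_run
```

The same functionality is importable: `gxekit.mr.run_mr_battery`,
`gxekit.survival.sliding_removal_sensitivity`, `gxekit.burden.burden_scan`,
and friends.

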