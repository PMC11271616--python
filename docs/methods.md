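# Methods

`medigut` implements a trivariate case-control analysis linking a
Mediterranean-diet score, gut-microbiota taxa abundances, and binary
disease status, together with a synthetic cohort generator that provides
a known ground truth for every estimator in the chain. This note records
the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic tests do and do not establish.

## Diet scoring

The alternative Mediterranean diet score (aMED) used here has seven
components — fruit, vegetables, legumes, whole-grain foods, fish,
processed-and-red meat combined, and the MUFA:SFA ratio — because the
underlying food-frequency instrument does not capture nuts or alcohol.
The two absent components are structurally absent, not zero-scored: the
maximum remains 7. A component earns one point when intake strictly
exceeds the sex-specific median intake of the eligible controls (strictly
below for meat); exact equality earns nothing.

Decisions where the convention was open:

* **Median convention.** Even-sized strata use the midpoint of the two
  central order statistics (the standard sample median).
* **MUFA:SFA** is formed per participant before the median is taken, so
  the cut-off is the median *ratio*, not the ratio of medians. These two
  differ whenever fat intakes are skewed.
* **Control medians are computed after the FFQ eligibility exclusions**
  (≥15 missing items, energy < 500 or > 3500 kcal/day). Eligibility
  precedes all statistics; a record excluded for data quality should not
  shape the reference cut-offs. Both energy bounds are exclusive, so 500
  and 3500 kcal/day exactly are kept.

## Taxa preparation

Counts are centred log-ratio (CLR) transformed with a pseudo-count of
0.5: `clr[s,t] = ln(n[s,t]+0.5) − mean_t ln(n[s,t]+0.5)`. The CLR is
computed over **all** taxa of a sample; the prevalence filter (relative
abundance ≥ 0.01% in at least `ceil(0.10 · n_samples)` samples, on raw
counts without pseudo-count) only restricts which taxa enter the
downstream screens. Natural log is used; any other base rescales the
Z-scored values identically. Presence/absence flags always come from raw
counts, never from CLR values. Count tables are read and written as TSV.

## Regression screens

Three families of models, each emitting estimate, SE, Wald 95% CI,
two-sided p, and a Benjamini–Hochberg q computed within the screen:

* diet → disease: ML logistic, adjusted for age at FFQ completion, sex
  and total energy.
* taxa → disease: robust logistic of status on the Z-scored CLR value,
  adjusted for library size (per 10⁴ reads, for conditioning), Bristol
  stool group (hard/medium/loose), age and sex.
* diet → taxa: robust linear regression of the raw CLR value on the
  Z-scored diet measure, with the same covariates plus energy. Estimates
  with |β| ≥ 0.70 are labelled strong.

The robust estimator is a Mallows-type robust quasi-likelihood fit: the
quasi-score uses Huber-truncated Pearson residuals (c = 1.345, 95%
Gaussian efficiency) recentred by their model-implied expectation so the
estimating equation remains Fisher-consistent; for the Gaussian family
this reduces to Huber M-estimation with MAD scale, and as c → ∞ both
families recover maximum likelihood exactly. Design-leverage
down-weighting (`x_weights="hat"`, weights √(1−hᵢᵢ)) is available but
**off by default**, matching the default settings of the reference
robust-GLM implementation this estimator follows. Standard errors are the
M-estimation sandwich; Newton steps fall back to a pseudo-inverse when a
saturated logistic makes the derivative singular, and such fits carry a
separation flag.

Mediator candidates are taxa with raw P < 0.05 (not q) both in the
(aMED-or-fiber) → taxon screen and in the taxon → disease screen;
q-values are reported alongside but do not gate selection.

## Causal mediation

For one diet measure, one taxon mediator and the shared covariate set
(energy, library size, Bristol group, age, sex), two fitted models are
combined in the potential-outcomes framework:

* mediator: Gaussian, `CLR ~ diet + covariates`;
* outcome: logistic, `disease ~ diet + CLR + covariates`.

Uncertainty is propagated quasi-Bayesianly: 10,000 coefficient vectors
are drawn from multivariate normals at the estimates with the fits'
covariances. Per draw, counterfactual mediator values m(a) at the
control/treated exposure levels (default 0 and 1 — one point of the raw
aMED, one SD of a standardized nutrient) are simulated **including
Gaussian residual noise** at the fitted residual SD; omitting the noise
would bias the averaged probabilities through the logistic nonlinearity.
The same residual-noise draws are reused for the two exposure arms
(common random numbers), which reduces Monte-Carlo variance of the
indirect effect without changing its expectation. Each participant's
outcome probability is evaluated on the four exposure/mediator
combinations; the reported ACME and ADE are the averages of the
treated-side and control-side decompositions, so ACME + ADE equals the
total effect exactly within every draw. Point estimates are means over
draws, intervals are percentile, and P = 2·min(frac ≤ 0, frac ≥ 0).
Odds-ratio-scale effects are formed from the draw-wise mean
counterfactual probabilities, averaging the two decompositions on the
log-OR scale. The proportion mediated is the median of draw-wise
ACME/TE, flagged unstable whenever the TE interval includes zero. By
default the two input models are ML fits; robust fits are accepted, and
their sandwich covariance is then used as the quasi-posterior.

A mediator is classified *consistent* when its indirect effect is
significant (P < 0.05) with the same sign as the total effect, and
*competitive* when it significantly opposes the total effect's sign.

**Calibration caveat.** The indirect-effect test is a product-of-paths
test. Under a *partial* null (one path active, the other zero) its
empirical size is close to nominal (0.047 at α = 0.05 over 300 synthetic
cohorts). Under the *complete* null (both paths zero) it is structurally
conservative — the draw distribution holds a single sign only when both
path estimates are individually large, giving a rejection rate near α²
rather than α (0/500 in our suite). This is a property of the estimator
class, not an implementation artefact.

## Ordination

Community-level variation uses the Aitchison distance (Euclidean on CLR
rows). PERMANOVA is marginal — one variable at a time, continuous or
dummy-coded categorical — via the Gower-centred inner-product matrix:
R² = SS(model)/SS(total) and a pseudo-F with P from free permutation of
sample labels, `P = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, 999
permutations by default, seed-controlled, with exhaustive enumeration
available for n ≤ 8. Marginal fitting was chosen because per-variable
explained percentages are the quantity of interest; a joint model would
make each R² order-dependent.

The diet-constrained principal axis residualizes both the CLR columns
and the constraining diet variable on any conditioning covariates (none
by default — the conditioned variant sits behind a flag), regresses each
residualized CLR column on the residualized constraint, and takes the
first left singular vector of the rank-1 fitted matrix. Scores are
standardized to unit variance and oriented to correlate positively with
the constraint; with no conditioners they are a perfect monotone image
of the constraint. The axis's disease association is an ML logistic fit
with the stool covariate set. The exact constrained-ordination variant
is a package choice (redundancy-analysis style on CLR values); other
variants (db-RDA, CAP) are deliberately out of scope.

## Eligibility

The Diet group requires an FFQ completed at age < 22 (age in years at
the FFQ date) passing the quality exclusions. The Diet-microbiota
subgroup additionally requires a stool sample within ±90 days of the FFQ
(inclusive at 90) and no antibiotic or corticosteroid exposure within
the 30 days before stool collection. With multiple records per
participant the earliest stool sample and its FFQ are kept. Every
exclusion is logged with a machine-readable reason, and the kept sets
plus the log exactly partition the roster.

## Synthetic cohort generator

The generator emulates the *post-bioinformatics* state of a pediatric
case-control diet-microbiome study; it does not simulate reads,
denoising, or longitudinal diet drift.

Per super-population individual: a latent healthfulness h ~ N(0,1)
drives log-normal food-component intakes around sex-specific medians
(males +15%), with the meat component loaded negatively. The
generation-time aMED is the count of components beyond their population
medians; its SD (≈1.98 under the default loadings) is computed by
Gauss–Hermite quadrature, and the standardized score s drives taxon
log-abundances `baseline_j + γ_j·s + ε` (ε SD 0.6, geometric
rank-abundance baseline), converted by softmax and drawn multinomially
at a log-normal library size (median 20,000, log-SD 0.35). Disease
follows `logit = α + β_direct·aMED + Σ b_j·CLR_j + covariates` with
β_direct = ln 0.66 per point by default and small age/sex effects. The
case-control sample is drawn by rejection until the requested quotas
(44/51 by default) are met; as in any case-control design the intercept
is design-biased while slopes remain consistent. Default n_taxa = 50 is
a desk-scale stand-in for the hundreds of genera/ASVs of a real study.
Bristol types follow a categorical distribution with roughly 20% hard /
73% medium / 7% loose; energy is log-normal with median 1100 kcal/day so
the FFQ exclusions have realistic bite; about 62% of participants carry
a stool sample; 3% of FFQs draw ≥15 missing items.

Two deliberate generator choices matter for interpretation:

* **Taxa are driven by the standardized realized aMED score, not by h
  directly.** This makes diet → taxa a genuine mediation path, so the
  true ACME of "set the aMED to a" is exactly defined and computable by
  brute-force counterfactual simulation (`oracle_acme`). In the oracle,
  taxa other than the mediator follow the exposure condition: their
  response to diet belongs to the direct path of the single-mediator
  estimand.
* **Marginal food-intake distributions are log-normal.** The source
  instrument's true marginals are unknown; log-normal is a generator
  choice, with medians anchored to plausible adolescent intakes
  (fruit 150, vegetables 120, legumes 10, whole-grain foods 50, fish 20,
  meat 80 g/day for females). The fiber loading is calibrated once so
  that Spearman ρ(fiber, aMED) ≈ 0.71 at n = 2000.

What the generator does **not** reproduce: overdispersed zero-inflated
taxa beyond the multinomial/log-normal structure, diet-race or
diet-Bristol confounding (race is pure noise metadata, so its PERMANOVA
R² is null by construction), batch effects, and FFQ item-level
measurement error. Passing tests therefore establish correctness of the
estimators under the generative model's assumptions, not robustness to
every feature of real amplicon data.

One empirically relevant subtlety the generator *does* reproduce:
because the analysis rescoring uses sampled control medians, the
measured aMED is an error-prone version of the generation-time score.
This measurement error leaks part of the direct diet effect into the
mediator coefficient and attenuates the estimated ACME by roughly 30%
even at large n. Estimator-recovery tests therefore use the ground-truth
score as the exposure, isolating the mediation machinery from exposure
measurement error; with it, the 95% interval covers the counterfactual
oracle in 92 of 100 synthetic cohorts at n = 500.

## Problem sizes and seeds

All randomized stages take explicit seeds and are bit-reproducible.
Simulation-based tests use cohorts of 160–1,000 participants, 1,000
quasi-Bayesian draws for interval checks, 100-seed coverage runs, and a
500-seed null calibration with 20 taxa — sizes chosen so the whole suite
exercises every estimator at meaningful power on a single CPU. The
acceptance script regenerates everything it reports from scratch at
n = 2000 (calibration), n = 95 (study-scale cohort analyses), and
n = 500 (mediation recovery).
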