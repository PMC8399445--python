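# Methods

## Model and estimands

For one candidate pair, exposure $a$ is a CpG probe's M-value at the
pre-seroconversion visit (PSV), mediator $m$ a metabolite abundance at the
seroconversion visit (SV), outcome $Y$ the binary islet-autoimmunity (IA)
status, and $c$ the covariate vector (HLA-DR3/4 indicator, age at PSV in
years, time PSV→SV in years, sex, optionally measurement platform).  Two
parametric models are fitted:

* mediator (linear): $m = \beta_0 + \beta_1 a + \beta_2'c + \varepsilon$,
  $\varepsilon \sim N(0,\sigma^2)$, by OLS **on controls only** —
  in a case–control sample the controls approximate the source population
  when the outcome is rare there;
* outcome (logistic): $\operatorname{logit}P(Y{=}1\mid a,m,c) =
  \theta_0+\theta_1 a+\theta_2 m+\theta_3 am+\theta_4'c$, by maximum
  likelihood on the full case–control sample (intercepts are biased by
  design, slopes are not).

Under the rare-outcome approximation (odds ratios ≈ risk ratios) the
natural direct and indirect effects for an exposure contrast
$a_0 \to a_1$ have the closed forms implemented in
`mediation.effects`; the total effect decomposes exactly as
$\log TE = \log NDE + \log NIE$, which the code guarantees by
construction and the tests assert at machine precision.  The interaction
term $\theta_3$ is always included; setting it to zero recovers the
product-of-coefficients $\theta_2\beta_1(a_1{-}a_0)$, asserted as a
property test.  The NIE under this parameterization does not involve the
covariate conditioning values; the NDE does, and conditions at the
analysis-sample covariate means by default (configurable to zeros or a
supplied vector — the choice is genuinely open, and only NIE comparisons
are scale-free across choices).

The default contrast is $a_0{=}0 \to a_1{=}1$ on the M-value scale;
because M-value units are arbitrary, a per-SD contrast can be configured
instead.

## Inference

* **Delta method.** $\operatorname{se}(\log NIE)$ propagates the
  covariance of $(\beta_1,\theta_2,\theta_3)$ — block-diagonal across the
  two independently fitted models — through the analytic gradient;
  $\sigma^2$ is held fixed (it does not enter the NIE), an approximation
  matching common practice.  Wald p-values from the normal reference.
* **Bootstrap.** Percentile intervals from B resamples drawn with
  replacement *within* case and control strata, preserving the
  case–control design (the design fixes those margins, so resampling
  respects them; unstratified resampling is not offered).  Both models
  are refitted per replicate, the mediator again on the resampled
  controls only.  Replicates with separated or non-convergent outcome
  fits are dropped and counted; more than 5% dropped flags a warning on
  the estimate.  Quantiles use linear interpolation of order statistics
  (`numpy.quantile` default), fixed so intervals are bit-reproducible
  given a seed.  The study-scale default is B = 10,000; the demo and the
  simulation studies use B = 500, which the coverage study shows is
  already near-nominal at those sample sizes.
* **FCR.** Pairs are selected by Benjamini–Hochberg on the delta-method
  p-values at q = 0.05 (equivalent to FDR-adjusted p < q); the R selected
  pairs' intervals are recomputed from the persisted replicate vectors at
  level $1-Rq/m$ (never refitting), and significance is 0-exclusion on
  the log odds scale.  Selection via delta p-values with intervals via
  bootstrap mirrors the split between ranking and interval construction
  elsewhere in the pipeline; the FCR guarantee permits any fixed
  selection rule.  The two temporal directions form separate families by
  default (`fcr.joint: true` pools them).

## Screening

Association screen: two-sided slope p from simple linear regression of
metabolite on probe — identical to the Pearson correlation test, and
direction-symmetric, so regressing probe on metabolite would change
nothing.  Outcome screens: Wald p for the feature in unadjusted logistic
regression of case status, computed once per feature and cached (a
result-equivalent reordering of screening pair-by-pair).  All three
screens use a nominal α = 0.01 and are deliberately not
multiplicity-adjusted: this stage only prunes the pair universe, and
error control happens at the FCR stage.  Screens are unadjusted for
covariates by default (`screen.adjust_platform: true` adds platform to
the logistic screens).  Features with separated screens are dropped with
a logged reason rather than crashing the scan.

## Synthetic cohorts

`simulate.simulate_cohort` draws an explicit source population
(default 20,000), generates covariates with marginals mimicking the study
cohort (sex Bernoulli(0.5), DR3/4 Bernoulli(0.23), age U(0.7, 20.3) y,
time PSV→SV U(0.3, 2.0) y, platform Bernoulli(0.5)), plants
`n_causal_pairs` mediation triplets through the two models above, draws
the outcome, and then samples exactly `n_cases`/`n_controls` without
replacement — so case oversampling, the controls-only fit and the
rare-outcome approximation are genuinely exercised, and a population
realizing too few cases is an explicit error naming the achieved count.
Defaults are the study's conditions: 92 cases / 91 controls, a rare
outcome ($\theta_0=-4.5$ keeps source prevalence around 3%, asserted
< 5% by simulation), and planted effects $\theta_2{=}0.4$,
$\theta_3{=}0.2$, $\beta_1{=}-0.6$ giving log NIE $=-0.36$ per pair (NIE
odds ratio ≈ 0.70, the middle of the published significant range), with
the metabolite raising risk and methylation suppressing the metabolite —
the protective-through-reduction structure the study reports.  Feature
panels default to 300 probes × 60 metabolites; the full-study universe
(199,243 × 1,905 = 379,557,915 pairs) is declared arithmetically in run
manifests and never materialized.

Measurement details emulated: an additive platform batch shift on
M-values (mean shift only — the analysis handles platform by covariate
adjustment, so a mean shift is the relevant failure mode), and metabolite
abundances on a positive scale (per-feature baseline 10 with spread
U(0.5, 2.0)) so the CV-based QC is meaningful.  The outcome model uses
the baseline-centered mediator; the natural effects are invariant to a
location shift of the mediator, so ground truth is unaffected.  For
reverse-direction triplets (metabolite at PSV driving DNAm at SV, planted
symmetrically on request) the exposure is a metabolite, and the recorded
unit contrast starts at the baseline abundance (truth table columns
`a0`/`a1` make this explicit).

Ground-truth natural effects are computed from the generating
coefficients by the same closed forms the estimator targets — and
validated against `simulate.monte_carlo_effects`, an independent
potential-outcome oracle that simulates counterfactual mediators
$M(a)$ and binary outcomes $Y(a, M(a^*))$ directly (independent draws
per arm) and forms odds ratios from realized counts.  The oracle shares
no code with the closed forms; agreement within 3 Monte-Carlo standard
errors over a randomized coefficient grid at 10⁷ draws is an acceptance
test.

What the generator does **not** emulate: bimodal M-value distributions,
probe–probe correlation structure, metabolite missingness or annotation
ambiguity, longitudinal visits beyond PSV/SV, or dietary covariates.
Passing tests therefore establish correctness of the statistical
machinery under the assumed models, not robustness to those real-data
features.

## Numerical choices

* Model fits inside the mediation core use a compact internal engine
  (`_fit.py`): OLS via normal equations with a pivoted rank check that
  names collinear columns, and Newton–Raphson logistic regression with a
  separation heuristic (diverging linear predictor with near-perfect
  classification, or a singular Hessian en route).  The percentile
  bootstrap refits both models per replicate, so per-fit overhead
  dominates simulation studies; the engine is validated
  coefficient-by-coefficient (and SE-by-SE) against statsmodels in the
  unit tests.  Screens and cohort statistics go through
  statsmodels/scipy directly.
* The CV filter reads "more than two absolute deviations from the
  median" as a median ± 2×MAD band on the CV distribution (unscaled MAD);
  the deviation count is configurable.  An absolute tolerance of
  1e-10·(1+|median|) keeps exactly-tied CVs (MAD = 0) from being flagged
  by floating-point noise; a single metabolite is therefore never
  excluded.  MAD-based filters are not strictly idempotent in
  pathological configurations; on realistic data (tested) a second
  application removes nothing.
* The low-abundance sample filter is a `median − k·MAD` rule on total
  abundance with k = 3 by default and `k = inf` disabling it; the rule is
  intentionally conservative about gross dropouts and will clip ~1% of
  Gaussian-tailed samples.
* Probe annotation positions are 1-based.  Missing values anywhere in
  analyzed matrices are an error — the pipeline is complete-case by
  contract, no imputation.
* All randomness flows from one mandatory seed; stage and per-pair seeds
  are derived by hashing (kept below 2³¹), so per-pair bootstrap results
  do not depend on how many pairs ran before them.

## Simulation-study sizes

The recovery study uses 200 cohorts of 500 cases + 500 controls drawn
from populations of 60,000 with a single planted pair
($\theta_2{=}0.4$, $\theta_3{=}0.2$, $\beta_1{=}-0.5$, true log NIE
$-0.3$) and B = 500, with no platform shift so the measured exposure is
the generating exposure (the batch-shift pathway is exercised separately
by the pipeline tests; with a shift present, the omitted platform×mediator
product term induces a small known attenuation that is not the
estimator property under test).  The null-FCR study uses 200 studies of
50 null pairs whose point estimates and parametric replicate vectors are
drawn directly from the null sampling distribution — the FCR machinery
(selection, re-levelling, coverage bookkeeping) is identical regardless
of where replicate vectors came from, and mediation-sourced vectors are
exercised end-to-end elsewhere.  The demo pipeline runs 200 participants,
300×60 features, 5 planted pairs, B = 500, both directions.

## Known limitations

Single continuous mediator with a binary rare outcome only; no exact
(non-rare) odds-ratio mediation, multiple mediators, or sensitivity
analysis for unmeasured confounding.  The rare-outcome closed forms carry
O(prevalence) bias, visible only at prevalences well above the <5%
regime the generator enforces.  Enrichment reproduces the
over-representation *engine* (hypergeometric, with the reference universe
restricted to genes mappable from the probe panel and the <5-reference /
<2-analysis exclusions applied as an either-bound by default,
configurable to the literal conjunction); external enrichment services
with their own internal universe bookkeeping will not match numerically.
meQTL lookup is out of scope beyond joining a user-supplied table.
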