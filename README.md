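# epimediate

Counterfactual mediation screening for paired omics in a longitudinal
case–control study of islet autoimmunity (IA), the autoimmune process that
precedes type 1 diabetes.

The scientific question: does a metabolite, measured at seroconversion
(SV), **mediate** the effect of DNA methylation at a CpG probe, measured at
the preceding autoantibody-negative visit (PSV), on the risk of developing
IA?  Because exposure precedes mediator, a causal mediation model is
temporally defensible; because IA is rare in the source population and the
study oversamples cases, the analysis needs case–control-aware estimation.

`epimediate` implements the full discovery pipeline on top of numeric
matrices of normalized methylation M-values and metabolite abundances:

1. **QC** — metabolite coefficient-of-variation outlier filter
   (median ± 2 MAD of the CV distribution) and a low-total-abundance
   sample filter.
2. **Screening** — for every probe–metabolite pair, simple linear
   regression of metabolite on probe plus two unadjusted logistic screens
   of each feature against case status, all at a nominal p < 0.01 (no
   multiplicity adjustment at this candidate-filtering stage).  Both
   temporal directions are screened (DNAm@PSV → metabolite@SV and
   metabolite@PSV → DNAm@SV).
3. **Mediation** — per candidate pair, with exposure $a$, mediator $m$,
   covariates $c$ (HLA-DR3/4, age at PSV, time PSV→SV, sex, and optionally
   measurement platform):

   $$m = \beta_0 + \beta_1 a + \beta_2' c + \varepsilon,\qquad
     \varepsilon \sim N(0, \sigma^2)$$
   $$\operatorname{logit} P(Y{=}1) = \theta_0 + \theta_1 a + \theta_2 m
     + \theta_3\, a m + \theta_4' c$$

   The mediator model is fitted on **controls only** (rare-outcome
   approximation for a case–control design).  Natural effects on the log
   odds-ratio scale for an exposure change $a_0 \to a_1$:

   $$\log \mathrm{NIE} = (\theta_2 \beta_1 + \theta_3 \beta_1 a_1)(a_1 - a_0)$$
   $$\log \mathrm{NDE} = \bigl(\theta_1 + \theta_3(\beta_0 + \beta_1 a_0
     + \beta_2' c + \theta_2 \sigma^2)\bigr)(a_1 - a_0)
     + \tfrac12 \theta_3^2 \sigma^2 (a_1^2 - a_0^2)$$

   with $\log\mathrm{TE} = \log\mathrm{NDE} + \log\mathrm{NIE}$ exactly.
   Inference: multivariate delta-method SE for the log NIE (Wald p-values)
   and a case/control-stratified percentile bootstrap (default B = 10,000)
   for confidence intervals.
4. **FCR adjustment** — Benjamini–Hochberg selection on the delta-method
   p-values at q = 0.05, then Benjamini–Yekutieli False-Coverage-Rate
   re-levelling of the selected pairs' bootstrap intervals to
   $1 - Rq/m$; a pair is significant when its adjusted interval excludes
   0 on the log odds scale.
5. **Over-representation** — the top-k probes by delta-method p are mapped
   to genes and tested pathway-by-pathway against a GMT file with the
   one-sided hypergeometric test (reference universe = genes mappable from
   the full probe list; pathways with <5 reference genes or <2 analysis
   genes excluded), BH-adjusted.

A first-class synthetic-data generator (`epimediate.simulate`) creates
case–control cohorts with planted mediation triplets, platform batch
shifts and known ground-truth effects, and is what the test suite and the
demo run on.  Real data matrices in TSV/CSV are read by `epimediate.io`.

## Worked example

```sh
epimediate run configs/demo.yaml --outdir results/demo
epimediate report results/demo
```

The demo simulates 200 participants (100 IA cases, 100 controls), 300
probes × 60 metabolites with 5 planted protective mediation triplets
(true NIE odds ratio ≈ 0.70 per unit M-value), screens all 18,000 forward
pairs, and bootstraps the survivors with B = 500.  Typical output
(abridged; seed 7):

```
== Significant pairs after FCR adjustment (fcr_dnam_psv) ==
probe_id metabolite_id   nie_or  nie_or_ci_low  nie_or_ci_high    p_nie
cg000001       met0001 0.518050       0.259483        0.842528 0.011102
cg000003       met0003 0.437237       0.206754        0.667807 0.001474
cg000004       met0004 0.384592       0.168952        0.611558 0.000106

== Significant pairs after FCR adjustment (fcr_met_psv) ==
zero significant pairs
```

Reading: for pair (cg000001, met0001) the estimated natural indirect
effect odds ratio is 0.52 — per unit increase in the probe's M-value, the
odds of islet autoimmunity transmitted *through* the metabolite are
roughly halved — with an FCR-adjusted 98.6% CI of (0.26, 0.84) that
excludes 1, so the pair is declared significant.  All planted pairs are
protective through a metabolite the exposure suppresses, which is the
structure the generator plants; the reverse temporal direction yields no
significant pairs, as nothing was planted there.

Every stage writes TSVs plus a JSON manifest into the results directory,
any stage can be rerun from those intermediates
(`epimediate fcr configs/demo.yaml --outdir results/demo`), and the whole
run is byte-reproducible given the config's seed.

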