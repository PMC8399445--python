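# Demo study: synthetic cohort, 200 participants, 300 probes x 60
# metabolites, strong planted mediation, reduced bootstrap (B=500).
seed: 7
output_dir: results/demo
simulate:
  n_population: 20000
  n_cases: 100
  n_controls: 100
  p_probes: 300
  q_metabolites: 60
  n_causal_pairs: 5
  theta0: -5.0
  theta1: -0.8
  theta2: 0.8
  theta3: 0.2
  beta1: -0.8
screen:
  alpha: 0.01
  directions: [dnam_psv, met_psv]
mediate:
  b_reps: 500
  ci_level: 0.95
fcr:
  q: 0.05
enrich:
  top_k: 100
  min_ref: 5
  min_analysis: 2
declared_universe:
  n_probes: 199243
  n_metabolites: 1905
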