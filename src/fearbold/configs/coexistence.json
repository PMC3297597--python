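{
  "_comment": [
    "Coexistence scenario: Lotka-Volterra background fitness enabled, with",
    "the bold phenotype's competitive effects (a_fb, a_bb) stronger than the",
    "fearful phenotype's (a_ff, a_bf) - individuals that risk more when",
    "confronted with predators are assumed more aggressive in competition.",
    "The original study prints the corresponding parameter values only in",
    "figures; all values here are reconstructions chosen once so that both",
    "phenotypes persist, the mean F-frequency over the trailing window",
    "decreases with population size, and the fluctuation strength decreases",
    "with population size.",
    "Sweep the population size with: sweep_axes = {\"n_total\": [120, 180, 240]}"
  ],
  "n_total": 180,
  "max_age": 5,
  "n_attacks": 10,
  "n_disturbances": 10,
  "beta": 0.7,
  "p_capture_f": 0.12,
  "p_capture_b": 0.2,
  "energy_gain": 10.0,
  "energy_cost_escape": 0.2,
  "repro_scale": 1.0,
  "risk_mode": "frequency_dependent",
  "competition": {
    "r_f": 2.4,
    "r_b": 1.8,
    "a_ff": 0.008,
    "a_fb": 0.010,
    "a_bf": 0.002,
    "a_bb": 0.012
  },
  "init_freq_f": 0.5,
  "init_age_distribution": "uniform",
  "max_seasons": 100000,
  "n_replicates": 1000,
  "base_seed": 0
}
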