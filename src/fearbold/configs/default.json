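{
  "_comment": [
    "Baseline scenario for the fearfulness-vs-boldness simulation.",
    "The original study reports its Results-section parameter values only in",
    "figures that are not machine-readable; every value below is therefore a",
    "reconstruction, not a printed number. The values are chosen once to sit",
    "in the qualitative regime the study describes: fearfulness favored in",
    "small populations, boldness in large ones, with an interior maximum of",
    "the fixation frequency in the attack count at moderate population size."
  ],
  "n_total": 100,
  "max_age": 5,
  "n_attacks": 25,
  "n_disturbances": 25,
  "beta": 0.2,
  "p_capture_f": 0.05,
  "p_capture_b": 0.3,
  "energy_gain": 10.0,
  "energy_cost_escape": 0.1,
  "repro_scale": 1.0,
  "risk_mode": "frequency_dependent",
  "competition": null,
  "init_freq_f": 0.5,
  "init_age_distribution": "uniform",
  "max_seasons": 100000,
  "n_replicates": 1000,
  "base_seed": 0
}
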