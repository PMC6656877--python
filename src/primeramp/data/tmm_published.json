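{
  "name": "TMM",
  "terms": ["intercept", "delta_g", "i_x", "delta_g:i_x"],
  "coefficients": [-5.6177, -1.5448, 0.3279, 0.1837],
  "standard_errors": null,
  "wald_p_values": [1.8e-08, 7.35e-12, 0.0818, 1.67e-05],
  "log_likelihood": null,
  "aic": null,
  "n_obs": 908,
  "cutoffs": {"high_specificity": 0.839, "youden": 0.461},
  "provenance": "Published thermodynamic mismatch model (TMM): logistic regression of PCR amplification status on annealing free energy (delta_g, kcal/mol), the 3'-hexamer mismatch position closest to the 3' terminus (i_x, 0..6) and their interaction; final fit on the full 908-pair IGHV primer coverage data set. Cutoffs are on the probability scale (direction: greater)."
}
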