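{
  "schema_version": "1.0",
  "n_strains": 59,
  "mice_per_strain_per_arm": 8,
  "var_strain": 2250000.0,
  "var_strain_slope": 22500.0,
  "var_mouse": 640000.0,
  "var_resid": 1000000.0,
  "grand_mean": 6000.0,
  "day_effects": [0.0, -500.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
  "cocaine_acute_effect": 4000.0,
  "ramp": [0.0, 800.0, 600.0, 400.0, 300.0],
  "expression_effect": 0.0,
  "conditioned_effect": 1000.0,
  "sex_effect": 500.0,
  "site_effect": 800.0,
  "sex_ratio": 0.5,
  "site_assignment": "JAX",
  "body_weight_mean": 22.0,
  "body_weight_sd": 2.0,
  "seed": 0
}
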