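# Reference IMK parameter sets per cell line and field condition.
# Units: alpha0, alpha_b in 1/Gy; beta0, beta_b in 1/Gy^2; a_plus_c in 1/h;
# delta dimensionless.
AGO1522:
  half_field:
    alpha0: 0.363
    beta0: 0.011
    a_plus_c: 0.034
  uniform:
    alpha0: 0.388
    beta0: 0.081
    a_plus_c: 1.684
  nte:
    alpha_b: 0.388
    beta_b: 0.031
    delta: 0.617
DU145:
  half_field:
    alpha0: 0.032
    beta0: 0.039
    a_plus_c: 2.509
  uniform:
    alpha0: 0.022
    beta0: 0.041
    a_plus_c: 1.506
  nte:
    alpha_b: 0.041
    beta_b: 0.023
    delta: 0.470
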