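# Striatum model configuration (units as in cortex.yaml).
# The striatum is GABA-rich; a larger share of the glutamate pool sits
# in GABAergic neurons and the cycling/TCA ratio constraints differ.
region: striatum
pools:
  conc_glu: 9.5
  conc_gln: 4.5
  conc_gaba: 2.8
  conc_asp: 2.3
  glu_fraction_glutamatergic: 0.75
  glu_fraction_gabaergic: 0.10
  glu_fraction_astroglial: 0.15
  intermediate_pool: 0.1
constraints:
  ratio_glu: 0.240
  ratio_gaba: 0.480
initial_rate_coefficients:
  glutamatergic_glu: 0.82
  gabaergic_glu: 0.02
  asp: 0.42
plasma:
  steady_enrichment: 0.45
  rise_tau: 1.0
fluxes:
  control:
    v_tca_glu: 0.379
    v_tca_gaba_net: 0.15167
    v_shunt: 0.040
    v_tca_a_net: 0.14
    v_pc: 0.045
    v_x: 1.0
    v_dil_glu: 0.05
    v_dil_gaba: 0.02
    v_dil_a: 0.10
    v_dil_gln: 0.10
  alcl3:
    v_tca_glu: 0.308
    v_tca_gaba_net: 0.140
    v_shunt: 0.035
    v_tca_a_net: 0.12
    v_pc: 0.04
    v_x: 1.0
    v_dil_glu: 0.05
    v_dil_gaba: 0.02
    v_dil_a: 0.10
    v_dil_gln: 0.10
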