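# Hippocampus model configuration (units as in cortex.yaml).
region: hippocampus
pools:
  conc_glu: 10.5
  conc_gln: 4.2
  conc_gaba: 2.4
  conc_asp: 2.6
  glu_fraction_glutamatergic: 0.80
  glu_fraction_gabaergic: 0.03
  glu_fraction_astroglial: 0.17
  intermediate_pool: 0.1
constraints:
  ratio_glu: 0.401
  ratio_gaba: 0.401
initial_rate_coefficients:
  glutamatergic_glu: 0.82
  gabaergic_glu: 0.02
  asp: 0.42
plasma:
  steady_enrichment: 0.45
  rise_tau: 1.0
fluxes:
  control:
    v_tca_glu: 0.50
    v_tca_gaba_net: 0.179
    v_shunt: 0.060
    v_tca_a_net: 0.15
    v_pc: 0.05
    v_x: 1.0
    v_dil_glu: 0.05
    v_dil_gaba: 0.02
    v_dil_a: 0.10
    v_dil_gln: 0.10
  alcl3:
    v_tca_glu: 0.43
    v_tca_gaba_net: 0.142
    v_shunt: 0.048
    v_tca_a_net: 0.13
    v_pc: 0.04
    v_x: 1.0
    v_dil_glu: 0.05
    v_dil_gaba: 0.02
    v_dil_a: 0.10
    v_dil_gln: 0.10
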