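# Cerebral-cortex model configuration.
# Units: fluxes umol/g/min, concentrations umol/g, time minutes,
# enrichment as a fraction of the pool.
region: cortex
pools:
  conc_glu: 11.0
  conc_gln: 4.0
  conc_gaba: 2.2
  conc_asp: 2.5
  glu_fraction_glutamatergic: 0.82
  glu_fraction_gabaergic: 0.02
  glu_fraction_astroglial: 0.16
  intermediate_pool: 0.1
constraints:
  # fixed V_cyc(Glu-Gln)/V_tca(Glu) and V_cyc(GABA-Gln)/V_tca(GABA)
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
    v_tca_glu: 0.554
    v_tca_gaba_net: 0.170
    v_shunt: 0.058
    v_tca_a_net: 0.15
    v_pc: 0.05
    v_x: 1.0
    v_dil_glu: 0.05
    v_dil_gaba: 0.02
    v_dil_a: 0.10
    v_dil_gln: 0.10
  alcl3:
    v_tca_glu: 0.405
    v_tca_gaba_net: 0.099
    v_shunt: 0.067
    v_tca_a_net: 0.13
    v_pc: 0.04
    v_x: 1.0
    v_dil_glu: 0.05
    v_dil_gaba: 0.02
    v_dil_a: 0.10
    v_dil_gln: 0.10
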