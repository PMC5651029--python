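# Methods

## The model

`neuroflux` models brain glucose oxidation and neurotransmitter
cycling as a three-compartment network: glutamatergic neurons,
GABAergic neurons and astroglia. Each compartment runs a TCA cycle
represented by a lumped α-ketoglutarate pool (carbons C2–C4) and an
oxaloacetate pool (C2, C3), both of size `intermediate_pool`
(default 0.1 μmol/g, small against the amino-acid pools). The
amino-acid pools are glutamate (split across the three compartments by
configurable fractions), GABA (GABAergic neurons only), glutamine
(astroglia only) and aspartate (exchanging with glutamatergic-neuron
oxaloacetate).

Steady-state fluxes (all μmol/g/min):

| flux | meaning |
|---|---|
| `v_tca_glu` | glutamatergic TCA cycle |
| `v_tca_gaba` / `v_tca_gaba_net` | total / net GABAergic TCA; total = net + `v_shunt` |
| `v_tca_a` / `v_tca_a_net` | total / net astroglial TCA; total = net + `v_pc` + `v_cyc_gaba_gln` |
| `v_cyc_glu_gln`, `v_cyc_gaba_gln` | glutamate–glutamine and GABA–glutamine cycles |
| `v_gad` | glutamate decarboxylase; = `v_shunt` + `v_cyc_gaba_gln` |
| `v_shunt` | GABA shunt (GABA → succinate in the GABAergic neuron) |
| `v_pc` | pyruvate carboxylase (astroglial anaplerosis) |
| `v_gln` | glutamine synthesis; = `v_cyc_glu_gln` + `v_cyc_gaba_gln` + `v_pc` |
| `v_x` | αKG ↔ glutamate (and OAA ↔ aspartate) exchange |
| `v_dil_*` | unlabelled dilution inflow/outflow of the four amino-acid pools |

`FluxSet.from_primary` builds a complete set from the ten independent
fluxes plus the two cycling/TCA ratio constraints, so every constructed
set satisfies the node balances exactly; `mass_balance_residuals`
verifies them. Anaplerotic carbon entering via `v_pc` leaves the
system as a matching glutamine efflux, closing the glutamine balance.

## Label routing

[1,6-¹³C₂]glucose yields [3-¹³C]pyruvate from both trioses, so the
pyruvate-C3 enrichment is taken equal to the plasma glucose C1/C6
enrichment, which rises as `E∞·(1 − exp(−t/rise_tau))`
(default `E∞` 0.45, `rise_tau` 1 min — the bolus protocol saturates
plasma quickly; `rise_tau = 0` gives a step).

Carbon map per turn: acetyl-C2 (from pyruvate C3) → αKG C4; OAA C2/C3
→ αKG C3/C2 at condensation; αKG C3/C4 pass the symmetric
succinate/fumarate pool and land on OAA C2/C3 with 50/50 scrambling
(αKG C2 reaches a carboxyl carbon and is lost as CO₂ on the next
turn). GAD maps glutamate C4/C3/C2 → GABA C2/C3/C4. The GABA shunt
returns GABA C2/C3 to GABAergic OAA with the same 50/50 scrambling
(GABA C4 is carboxyl-bound); this return is part of the carbon map and
can be disabled by setting `v_shunt = 0`. Pyruvate carboxylase
deposits pyruvate-C3 label on astroglial OAA C3 only (no
back-scrambling), whence Gln C2/C3. Astroglial uptake routes released
glutamate into the astroglial glutamate pool and GABA into the
astroglial TCA at the succinate level.

With fluxes at steady state the positional enrichments obey the linear
system `C_P · df/dt = Σ V_in f_src − (Σ V_out) f`, 32 states in all.
Measured tissue glutamate is the pool-fraction-weighted mix of the
three compartmental glutamate pools.

## Numerics

Two integrators share the same assembled system: LSODA
(`rtol 1e-8 / atol 1e-10`) and an exact matrix exponential of the
augmented autonomous system (state ⊕ plasma ⊕ constant). They agree to
< 1e-8 on the shipped configurations; the matrix-exponential path is
exact for arbitrarily stiff exchange rates and is used inside fitting
loops for speed (~2 ms per simulation) and as the independent
numerical oracle in tests, alongside a closed-form one-pool limit.
Enrichment starts at zero everywhere, stays within
[0, plasma enrichment], and total labelled carbon obeys an explicit
inflow/loss budget checked against the transition bookkeeping.

## Fitting

The six measured curves (Glu-C4, Glu-C3, GABA-C2, GABA-C3, Asp-C3,
Gln-C4) are fitted by bounded trust-region least squares (`scipy`
`least_squares`, trf) over the ten independent fluxes, iteration
budget 500, with three jittered starts (σ = 0.2 log-normal) guarding
against local minima. The cycling/TCA ratios are enforced by
construction, so they hold to machine precision in every result and
every Monte-Carlo replicate. Single-time-point data are rejected with
a pointer to the initial-rate estimators.

Weighting: unit weights by default. Because replicate noise in this
pipeline is heteroscedastic (multiplicative CV with an additive
enrichment floor), `fit_model(..., weighting="variance")` performs one
iteratively-reweighted pass, deriving per-point inverse-variance
weights `max(cv·ŷ, floor)²` from the unit-weight fit's own curves.
The recovery experiments use this estimator: at study-scale noise it
cuts the recovery SD of the GABAergic TCA flux from ≈5.4% to ≈4.0%
and keeps all recovery targets within ±10% across seeds. An explicit
per-point `weight` (variance) column always takes precedence.

Uncertainty is parametric bootstrap: Gaussian noise with
`SD = max(cv·value, floor)` (defaults 5% CV, 0.005 floor — the noise
family is a stated stand-in, the study's true inter-animal variance
being unknown) is added to the best-fit noiseless curves; each of 500
replicates is refitted from the point estimate; means and SDs of the
free fluxes are reported. Non-converged replicates are dropped and
counted, with a warning above 10%. Everything is deterministic given
the seed.

## Initial-rate estimators

For the single 10-min infusion arm, glucose oxidation is estimated
from the labelled amounts trapped in the amino-acid pools (see README
for the formulas). The ½ converts labelled three-carbon units to
glucose equivalents; 1/10 is the infusion time; 1/Glc₁ scales to fully
labelled substrate; the doubled terms (Glu-C3, Asp-C3, GABA-C4)
compensate the 50/50 succinate split of second-turn label; 0.82, 0.02
and 0.42 are the glutamatergic/GABAergic shares of the glutamate and
aspartate pools and live in the region configuration. The group-level
plasma enrichment Glc₁ defaults to 0.50 for the shipped table and is a
parameter everywhere. These estimators ignore label lost to CO₂,
lactate/alanine and glutamine cycling and therefore underestimate the
absolute rates; group contrasts survive because the bias is shared. No
correction is applied, by design.

## Region presets

One YAML per region ships pool sizes, glutamate partition, ratio
constraints and control/AlCl₃ flux presets. Cortex pools: Glu 11.0,
Gln 4.0, GABA 2.2, Asp 2.5 μmol/g, partition 0.82/0.02/0.16 —
literature-typical mouse values; hippocampus and striatum vary these
modestly (striatum more GABAergic: partition 0.75/0.10/0.15). Ratio
constraints: cortex and hippocampus 0.401/0.401, striatum 0.240/0.480.
Preset TCA and cycling rates are keyed to published regional estimates
for this experiment class; where a regional value is unpublished
(e.g. hippocampal `v_tca_glu`) a mid-range default (0.50) is used.
The cortical `v_shunt` presets (0.058 control, 0.067 AlCl₃) are
calibrated so that the neuronal glucose-oxidation definition below
reproduces the preset composite rates exactly.

Composite outputs: total neurotransmitter cycling
= `v_cyc_glu_gln + v_cyc_gaba_gln`; neuronal glucose oxidation
= `(v_tca_glu + v_tca_gaba_net)/2` — the net GABAergic term excludes
the shunt return so shunt carbon is not counted twice. For the
striatum this definition is not simultaneously consistent with the
preset composite rate and the ratio-derived GABAergic TCA rate; the
preset keeps a biologically plausible shunt (0.040) and lets the
composite follow.

## Synthetic data

The generator emulates the study design: infusion end points at 10,
30, 60, 90 min, 3 animals per point, 6 curves (72 records per region);
single-time-point group tables with 4 treatment arms and n = 6 per
group. Treatment effects are multiplicative on the control means
(defaults: AlCl₃ 0.75, restoration 0.93, control-intervention 0.97 —
matching the ~15–35% reductions and near-complete restoration seen in
this experiment class). Replicate noise is the same CV-plus-floor
family the fitting module assumes; draws below zero are clipped and
counted. What the generator does **not** emulate: inter-animal
correlation across metabolites, drifting plasma enrichment between
animals, regional covariance, or non-Gaussian outliers — so passing
recovery tests demonstrate estimator correctness under the stated
noise family, not robustness to every feature of real data.

## Known limitations

* The intermediate pools are lumped (no separate citrate/succinate
  states); kinetic detail faster than `v_x` is not resolved.
* Aspartate is attached to the glutamatergic compartment only.
* Lactate/pyruvate dilution is folded into the pool dilution fluxes
  rather than modelled as a distinct exchange.
* Blood–brain transport kinetics are not modelled; the plasma input is
  a fixed saturating exponential.
* Initial-rate estimates are downward-biased (see above) and carry no
  propagated SEM: they are point estimates per group.
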