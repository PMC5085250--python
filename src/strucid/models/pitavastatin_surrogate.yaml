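# Synthetic surrogate of a pharmacokinetic model of hepatic drug uptake
# with intracellular metabolism (3 states, 7 parameters, 1 output): drug
# in the medium (x1) enters hepatocytes by saturable transport (vmax, km)
# and passive diffusion (kd), effluxes back (ke), and is metabolised
# (kmet) to a metabolite (x3) with saturable clearance (kc, kx); the
# measured signal is the total intracellular amount x2 + x3.
#
# SYNTHETIC STAND-IN: the published uptake-model equations are in a
# supplement that is not redistributed here; this surrogate matches the
# published dimensions and verdict (structurally identifiable, verified at
# build time), not the original rate laws.
name: pitavastatin_surrogate
states: [x1, x2, x3]
parameters: [vmax, km, kd, ke, kmet, kc, kx]
inputs: []
odes:
  - -vmax*x1/(km + x1) - kd*x1 + ke*x2
  - vmax*x1/(km + x1) + kd*x1 - ke*x2 - kmet*x2
  - kmet*x2 - kc*x3/(kx + x3)
outputs: [x2 + x3]
initial_conditions: {x1: 1, x2: 0, x3: 0}
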