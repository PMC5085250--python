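# Steady-state variant of the hepatic-uptake surrogate (2 states, 6
# parameters): the extracellular amount is eliminated through the mass
# balance x1 = 100 - x2 - x3 (closed system, dose 100 known), leaving the
# intracellular drug (x2) and its metabolite (x3).
#
# SYNTHETIC STAND-IN: see pitavastatin_surrogate.yaml.
name: pitavastatin_ss_surrogate
states: [x2, x3]
parameters: [vmax, km, kd, ke, kmet, s]
inputs: []
odes:
  - vmax*(100 - x2 - x3)/(km + 100 - x2 - x3) + kd*(100 - x2 - x3) - ke*x2 - kmet*x2
  - kmet*x2
outputs: [s*(x2 + x3)]
initial_conditions: {x2: 0, x3: 0}
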