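# Two-state submodel {x1, x7} of the Arabidopsis circadian clock model:
# the LHY-mRNA and light-protein equations, with the excluded nuclear
# TOC1 protein x6 appearing as an unknown constant pseudo-parameter.
name: arabidopsis_sub_x1x7
states: [x1, x7]
parameters: [n1, g1, a, m1, k1, q1, p3, m7, k7, q2, x6]
inputs: [u]
odes:
  - n1*x6^a/(g1^a + x6^a) - m1*x1/(k1 + x1) + q1*x7*u
  - p3 - m7*x7/(k7 + x7) - (p3 + q2*x7)*u
outputs: [x1]
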