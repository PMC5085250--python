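# Three-layer MAPK signalling cascade with mixed feedback (reconstruction):
# states are the phosphorylated kinase fractions of each layer; the third
# layer inhibits activation of the first (negative feedback, Hill exponent
# n1 and threshold K1) and amplifies its own activation (positive
# feedback, exponent n2, threshold K2, strength alpha); totals s1t..s3t
# are unknown.  All three phosphorylated forms are measured.
#
# The published equations of this benchmark are in a supplement that is
# not redistributed here; these equations are a reconstruction from the
# printed description (layer structure, the 14-parameter list, and the
# mixed positive/negative feedback) and reproduce every published verdict
# for this model, including the three output-removal scenarios.
name: mapk
states: [x1, x2, x3]
parameters: [k1, k2, k3, k4, k5, k6, s1t, s2t, s3t, K1, K2, n1, n2, alpha]
inputs: []
odes:
  - k1*(s1t - x1)*K1^n1/(K1^n1 + x3^n1) - k2*x1
  - k3*x1*(s2t - x2) - k4*x2
  - k5*x2*(s3t - x3)*(1 + alpha*x3^n2/(K2^n2 + x3^n2)) - k6*x3
outputs: [x1, x2, x3]
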