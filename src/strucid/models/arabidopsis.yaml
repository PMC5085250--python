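# Two-loop genetic network of the circadian clock in Arabidopsis thaliana
# (interlocked LHY/TOC1 feedback loops, Michaelis-Menten degradation and
# Hill-type transcription; light input u(t)).  x1/x4 are LHY/TOC1 mRNA,
# x2-x3 and x5-x6 cytoplasmic/nuclear proteins, x7 a light-sensitive
# protein.  Only the mRNA concentrations (x1, x4) are measured.  The
# TOC1-transcription Hill coefficient is fixed at 2; the LHY coefficient
# `a` is treated as an unknown parameter, which keeps the model
# non-rational (28 unknown parameters in total).
name: arabidopsis
states: [x1, x2, x3, x4, x5, x6, x7]
parameters: [n1, n2, g1, g2, m1, m2, m3, m4, m5, m6, m7,
             k1, k2, k3, k4, k5, k6, k7, p1, p2, p3,
             r1, r2, r3, r4, q1, q2, a]
inputs: [u]
odes:
  - n1*x6^a/(g1^a + x6^a) - m1*x1/(k1 + x1) + q1*x7*u
  - p1*x1 - r1*x2 + r2*x3 - m2*x2/(k2 + x2)
  - r1*x2 - r2*x3 - m3*x3/(k3 + x3)
  - n2*g2^2/(g2^2 + x3^2) - m4*x4/(k4 + x4)
  - p2*x4 - r3*x5 + r4*x6 - m5*x5/(k5 + x5)
  - r3*x5 - r4*x6 - m6*x6/(k6 + x6)
  - p3 - m7*x7/(k7 + x7) - (p3 + q2*x7)*u
outputs: [x1, x4]
initial_conditions: {x1: 0, x2: 0, x3: 0, x4: 0, x5: 0, x6: 0, x7: 0}
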