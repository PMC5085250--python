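# NF-kB signalling pathway (two-compartment single-cell model with A20 and
# IkBa negative feedback; TNF stimulation u(t)).  States: IKK in neutral /
# active / inactive form (x1-x3), IKKa complexes (x4, x5), cytoplasmic and
# nuclear NF-kB (x6, x7), A20 protein and transcript (x8, x9), IkBa
# protein, nuclear IkBa and transcript (x10-x12), IkBa|NF-kB complexes
# (x13, x14) and a control-gene transcript x15 that is driven by nuclear
# NF-kB but feeds back on nothing.  Six standard observables.
name: nfkb
states: [x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11, x12, x13, x14, x15]
parameters: [a1, a2, a3, t1, t2, c1, c2, c3, c4, c5,
             c1a, c2a, c3a, c4a, c5a, c6a, c1c, c2c, c3c,
             i1, e1a, i1a, e2a, kprod, kdeg, kv, k1, k2, k3]
inputs: [u]
odes:
  - kprod - kdeg*x1 - k1*u*x1
  - k1*u*x1 - k3*x2 - k2*u*x2*x8 - kdeg*x2 - a2*x2*x10 + t1*x4 - a3*x2*x13 + t2*x5
  - k3*x2 + k2*u*x2*x8 - kdeg*x3
  - a2*x2*x10 - t1*x4
  - a3*x2*x13 - t2*x5
  - c6a*x13 - a1*x6*x10 + t2*x5 - i1*x6
  - i1*kv*x6 - a1*x11*x7
  - c4*x9 - c5*x8
  - c2 + c1*x7 - c3*x9
  - -a2*x2*x10 - a1*x6*x10 + c4a*x12 - c5a*x10 - i1a*x10 + e1a*x11
  - -a1*x11*x7 + i1a*kv*x10 - e1a*kv*x11
  - c2a + c1a*x7 - c3a*x12
  - a1*x6*x10 - c6a*x13 - a3*x2*x13 + e2a*x14
  - a1*x11*x7 - e2a*kv*x14
  - c2c + c1c*x7 - c3c*x15
outputs: [x7, x10 + x13, x9, x1 + x2 + x3, x2, x12]
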