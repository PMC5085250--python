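# Synthetic surrogate of an IL13-induced JAK/STAT signalling model
# (10 states, 23 parameters, 8 outputs, ligand input u): receptor
# activation (x1, x2), JAK phosphorylation with SOCS-mediated inhibition
# (x3, x7), cytoplasmic/nuclear phosphorylated STAT (x4, x5), SOCS mRNA
# and protein (x6, x7), a target-gene mRNA/protein branch (x8, x9) and a
# dephosphorylated-JAK pool (x10) whose readout is reported in arbitrary
# units.  The free receptor pool x1 and the nuclear STAT x5 are not
# measured.
#
# SYNTHETIC STAND-IN: the published reduced model equations are in a
# supplement that is not redistributed here.  This surrogate matches the
# published dimensions and the published identifiability structure,
# verified at build time: exactly {th11, th15, th17, th21, th22} are
# unidentifiable; th17 and th22 occur only through their product (an
# identifiable combination); th11, th15, th21 share a scaling symmetry
# with the unmeasured nuclear STAT x5, so fixing th11 makes the other two
# identifiable.
name: jakstat_surrogate
states: [x1, x2, x3, x4, x5, x6, x7, x8, x9, x10]
parameters: [th1, th2, th3, th4, th5, th6, th7, th8, th9, th10, th11,
             th12, th13, th14, th15, th16, th17, th18, th19, th20, th21,
             th22, th23]
inputs: [u]
odes:
  - th1 - th2*x1 - th3*u*x1
  - th3*u*x1 - th4*x2
  - th5*x2 - th6*x3 - th19*x3*x7/(th9 + x7)
  - th7*x3 - th8*x4 + th15*x5
  - th11*x4 - th12*x5
  - th21*x5 - th13*x6
  - th14*x6 - th16*x7
  - th10*x4 - th18*x8
  - th20*x8 - th23*x9
  - th6*x3 - th2*x10
outputs: [x2, x3, x4, x6, x7, x8, x9, th17*th22*x10]
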