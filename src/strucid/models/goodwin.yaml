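# Goodwin oscillator of transcriptional repression (1965): enzyme x1
# represses its own synthesis through the metabolite chain x1 -> x2 -> x3,
# with a Hill-type repression term of unknown exponent sigma (non-rational).
# Only the enzyme concentration x1 is measured.
name: goodwin
states: [x1, x2, x3]
parameters: [a, A, alpha, b, beta, gamma, delta, sigma]
inputs: []
odes:
  - a/(A + x3^sigma) - b*x1
  - alpha*x1 - beta*x2
  - gamma*x2 - delta*x3
outputs: [x1]
initial_conditions: {x1: 0.3617, x2: 0.9137, x3: 1.3934}
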