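# Uniform sampling ranges for the nondimensional sensitivity analysis.
# A2 starts at 1: for A2 in [0,1) the beta-catenin steady state can go
# negative and e, s respond non-monotonically.
d: [0.0, 6.0]
A1: [0.0, 120.0]
A2: [1.0, 2.0]
A3: [0.0, 2.0]
C1: [0.0, 5.0]
C2: [0.0, 2.5]
C3: [0.0, 2.5]
F1: [0.0, 2.5]
F2: [0.0, 25.0]
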