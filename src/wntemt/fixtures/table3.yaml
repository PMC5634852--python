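# Uniform sampling ranges for the dimensional sensitivity analysis.
# The D row sets the Dvl levels explored (fixed per analysis, not sampled).
# alpha2 starts at 0.01: below it the beta-catenin balance admits negative
# steady states and the outputs lose monotonicity.
D: [0.0, 4.0]
alpha1: [0.0, 0.12]
alpha2: [0.01, 0.02]
alpha3: [0.0, 0.2]
beta1: [0.0, 0.1515]
beta2: [0.0, 0.07576]
beta3: [0.0, 0.07576]
k0: [0.0, 0.025]
k1: [4.0e-3, 0.01]
k2: [0.0, 2.5]
IC_S: [0.0165, 10.0]
IC_B: [0.0, 0.825]
IC_E: [2.75e-3, 0.2]
IC_D: [0.0, 5.0]
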