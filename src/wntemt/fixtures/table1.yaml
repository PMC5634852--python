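# Dimensional rate constants of the Wnt/EMT switch model (nM, minutes).
alpha1: 0.01
alpha2: 0.01
alpha3: 0.001
beta1: 0.03
beta2: 0.03
beta3: 0.03
k0: 3.7e-3
k1: 0.01
k2: 1.0
IC_S: 3.3
IC_B: 0.33
IC_E: 0.033
IC_D: 0.67
n1: 3
n2: 2
n3: 2
n4: 5
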