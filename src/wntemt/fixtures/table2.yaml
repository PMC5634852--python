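# Published nondimensional constants (loss rates rounded to 1).
A1: 10
A2: 1
A3: 0.01
C1: 1
C2: 1
C3: 1
F1: 0.37
F2: 10
n1: 3
n2: 2
n3: 2
n4: 5
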