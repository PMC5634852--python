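# Exact nondimensionalization of table1 (loss rates 0.99, not rounded).
A1: 10
A2: 1
A3: 0.01
C1: 0.99
C2: 0.99
C3: 0.99
F1: 0.37
F2: 10
n1: 3
n2: 2
n3: 2
n4: 5
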