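# Supra-threshold Dvl pulse: Wnt on (d = 5.4) at tau = 20, off at tau = 50.
segments:
  - {time: 0, d: 0}
  - {time: 20, d: 5.4}
  - {time: 50, d: 0}
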