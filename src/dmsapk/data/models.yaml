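# Published Tc-99m DMSA kidney biokinetic parameter sets.
# Each model is F_S * sum_i a_i * exp(-ln2 / T_i * t); T_i: "inf" = no
# biological clearance for that component (rate 0).
icrp53:
  F_S: 0.5
  components:
    - {a: -1.0, T_h: 1.0}
    - {a: 1.0, T_h: inf}
evans:
  F_S: 0.4
  components:
    - {a: -1.0, T_h: 1.0}
    - {a: 1.0, T_h: 7.0}
current_study:
  F_S: 0.3
  components:
    - {a: -1.0, T_h: 1.1}
    - {a: 1.2, T_h: inf}
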