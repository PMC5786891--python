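# Example synthetic dataset: three families of ten 300-mers with distinct
# spectral signatures (period-2 motif, period-3 motif, uniform random).
seed: 7
families:
  - family_id: per2
    n_sequences: 10
    length: 300
    motif: AT
    mu: 0.02
  - family_id: per3
    n_sequences: 10
    length: 300
    motif: ACG
    mu: 0.02
  - family_id: unif
    n_sequences: 10
    length: 300
    mu: 0.02
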