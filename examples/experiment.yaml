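# A desk-scale experiment: strong planted signal, rare-ish outcome,
# HAN-Text versus two ablations. Increase n_patients and epochs for
# larger runs; every stage seed derives from the single seed below.
seed: 7
generator:
  n_patients: 3000
  prevalence: 0.02
  signal_rate_case: 0.9
  signal_rate_control: 0.02
embedding:
  dim: 32
  min_count: 5
  epochs: 3
models:
  - kind: han_text
    word_hidden: 16
    sent_hidden: 16
    attn_dim: 32
  - kind: hn
    word_hidden: 16
    sent_hidden: 16
  - kind: lstm
    word_hidden: 16
train:
  max_epochs: 6
  patience: 6
evaluation:
  cutoff: 0.02
  n_boot: 500
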