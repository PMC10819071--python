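# Full default training configuration (mirrors TrainConfig defaults).
# Reference setup: Adam lr 1e-4, batch 64, <=100 epochs with early stopping,
# feature width 128, 8 attention heads, 10 random seeds.

lr: 0.0001
batch_size: 64
max_epochs: 100
patience: 15
seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
split: scaffold            # scaffold | random
fractions: [0.8, 0.1, 0.1]
ablation: full             # full | no_graph | no_sequence
metric: null               # default: roc_auc (classification) / rmse (regression)

# model
dim: 128
seq_heads: 8
seq_layers: 4
fusion_heads: 8
rounds: 3                  # message-passing rounds K
aggregation: sum           # sum | mean
set2set_steps: 3
max_len: 256
dropout: 0.1

# featurization / vocabulary
explicit_h: null           # null: explicit H iff a functional-group pattern needs it
n_bins: 5                  # quantile bins for radius/weight property groups
fcs_min_freq: 5
fcs_max_token_len: 8
fcs_max_vocab: 1024
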