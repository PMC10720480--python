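# Desk-scale configuration: trains in minutes on one CPU.
# Intended for synthetic data, smoke tests and method development.
model:
  gnn_type: gcn
  protein_branches: [matrix2d]
  gnn_layers: 2
  hidden_dim: 32
  embed_dim: 32
  fc_dims: [64]
  dropout: 0.0
  pooling: mean
epochs: 12
lr: 2.0e-3
batch_size: 64
log1p: true
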