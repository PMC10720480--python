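# Benchmark-scale configuration matching the full published architecture:
# both protein branches, five GNN layers, wide fusion head.
# NOTE: training on Davis/KIBA-sized datasets at this scale requires
# accelerator hardware; on a single CPU it is impractically slow.
model:
  gnn_type: gin
  protein_branches: [tensor3d, matrix2d]
  gnn_layers: 5
  hidden_dim: 128
  embed_dim: 128
  fc_dims: [1024, 512]
  dropout: 0.2
  pooling: max
epochs: 100
lr: 5.0e-4
batch_size: 128
log1p: false
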