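# Methods

## Problem and model

The package predicts a continuous drug–target binding affinity from a
molecule's SMILES string and a protein's amino-acid sequence alone. The
design premise is that truncating long protein sequences (as fixed-length
sequence encoders must) discards binding-relevant information; both protein
encodings used here are *length-free*: any sequence maps to fixed-size
occurrence matrices whose cells are indexed by residue identity, not
position.

**Residue alphabet.** 21 symbols, the 20 standard amino acids plus the
wildcard `X`, in the fixed order A, C, D, E, F, G, H, I, K, L, M, N, P, Q,
R, S, T, V, W, X, Y. Any other letter (B, J, O, U, Z, …) encodes as `X`
rather than erroring, because real UniProt sequences contain such codes;
non-letters are rejected with the offending position. The order is part of
the serialization contract: a stored tensor is only interpretable with the
alphabet it was built under, so the featurization CLI embeds the alphabet
in its output container.

**k-mer tensor (k = 3, step 1).** Each window's residue triple is counted
*regardless of order*: the count is written at every index permutation, so
the 21³ tensor is symmetric under all axis permutations and the sum over
canonical (sorted) index triples equals `max(0, L − 2)` for a length-L
sequence. Sequences shorter than 3 produce the zero tensor instead of an
error so degenerate records can flow through batching. k is fixed at 3:
the tensor dimensionality is `21^k`, so other k values would change the
network input shape.

**Cartesian-product matrix.** All ordered position pairs (p, q), including
p = q, are tallied by residue pair, which makes the matrix exactly the
outer product of the residue-composition vector with itself: entry (a, b)
is `n_a · n_b` and the total is L². Although the construction reads as
order-sensitive, the full Cartesian product forces `n_a·n_b = n_b·n_a`, so
the matrix is necessarily symmetric; the test suite asserts the
outer-product identity as the ground truth of this featurization.

**Counts and scaling.** Raw integer counts are canonical. Because
Cartesian counts grow as L² (a 1,200-residue sequence yields cells near
10⁶), an optional `log1p` transform is exposed as a featurization flag
(default off). The CPU-scale training configurations enable it; without
compression the first convolution's activations span four orders of
magnitude across proteins of different lengths, which destabilizes
training at practical learning rates.

**Molecule graphs.** RDKit parses SMILES with default sanitization; heavy
atoms only, node order as RDKit reports it, each bond doubled into two
directed edges, no stored self-loops (the GCN adds `Â = A + I` itself) and
no edge attributes (none of the message-passing variants here consume
them). Atom features are the 78-dimensional one-hot scheme standard in
graph-based DTA models: element over a 44-symbol list with an "other"
bucket, degree 0–10, total H count 0–10, implicit valence 0–10, and an
aromaticity flag — exactly one hot slot per block, so feature rows sum to
4 or 5.

## Network

Three branches produce equal-width embeddings (`embed_dim`, default 128):

- **3D CNN** on the 21×21×21 tensor: three blocks of same-padding conv
  (kernel 3) → ReLU → window-2 max pool, channel widths 8 → 16 → 32,
  spatial path 21 → 10 → 5 → 2, then a linear projection from the 256-dim
  flattening.
- **2D CNN** on the 21×21 matrix: same structure with widths 16 → 32 → 64.
- **GNN** on the molecule graph: `gnn_layers` (default 5) stacked layers of
  one of three aggregation families, each followed by batch normalization
  then ReLU (layer → BN → ReLU order), then global pooling and a linear
  projection.
  - *GCN*: `σ(D̂^{-1/2}(A+I)D̂^{-1/2} H W)`, implemented edge-wise with
    per-edge normalization `1/√(d̂_src d̂_dst)`.
  - *GAT*: single-layer LeakyReLU (slope 0.2) attention on concatenated
    transformed features, softmax-normalized over each node's first-order
    in-neighborhood including a self-loop; multiple heads concatenate, so
    `hidden_dim` must be divisible by `gat_heads` (default 1).
  - *GIN*: `MLP((1+ε)h_v + Σ_{u∈N(v)} h_u)` with a two-layer
    ReLU MLP and ε a learnable scalar initialized at 0.

The active branch embeddings (1–3 of them, matching the nine ablation
wirings 2D/3D/2D+3D × GCN/GAT/GIN) are concatenated and passed through
fully connected layers (`fc_dims`, default [1024, 512]) with ReLU and
dropout (default 0.2), ending in one linear output unit on the scale of
the training labels.

Choices the architecture description leaves open, resolved here: the GNN
nonlinearity is applied at every layer including the last before pooling;
batch normalization sits between the aggregation and the ReLU; global
pooling defaults to featurewise max with a `mean` option. CNN depths,
widths and FC sizes are set at the scale customary for this model family
and are all exposed in `ModelConfig`.

## Training

Adam (lr 5e-4 by default, β = 0.9/0.999) minimizes MSE over shuffled
minibatches (default 128). After every epoch the validation MSE and CI are
recorded; the returned model carries the parameters of the epoch with the
lowest validation MSE (best-checkpoint selection). One integer seed fixes
parameter initialization (Glorot uniform), minibatch order and dropout, so
a rerun with equal seed and data reproduces losses bitwise. A non-finite
training loss aborts with the epoch and batch in the message rather than
silently corrupting the checkpoint.

The numerical substrate is a small reverse-mode autodiff engine on
float64 numpy arrays (`kcdta.nn.autograd`). Convolutions gather im2col
patches through cached index maps and contract with `tensordot`; the
input gradient is computed as a second gather (the transposed
convolution) rather than a scatter-add, since `np.ufunc.at` is orders of
magnitude too slow for the training loop. Max pooling uses disjoint
windows, so its backward pass is a unique-index assignment. Every operator
is finite-difference checked in the test suite; the checks position inputs
away from ReLU/max kinks, where the central difference is not a valid
oracle (zero-initialized biases with sparse integer count inputs otherwise
place pre-activations exactly on the kink).

## Evaluation protocols

- **Six-part CV** (Davis/KIBA style): the dataset splits into six equal
  parts; one is the fixed test set, the remaining five rotate as
  validation folds (train on four, select on one), and each fold's best
  checkpoint is scored on the test part. Published benchmark fold indices
  are used verbatim when present; fold `i` trains with model seed
  `seed + i`, logged.
- **Random 4:1** split (Metz style), repeatable per seed.
- **Temporal** split (PDBBind style): train ≤ 2011, validation = 2012,
  test ≥ 2013, by the record's publication year.

**Metrics.** CI counts ordered pairs with distinct true affinities:
prediction ties score 0.5, truth ties are excluded from the denominator —
the standard concordance convention (a literal reading of the normalizer
as "pairs in the correct order" would make the index degenerate). The CI
implementation is cross-checked against a double-loop oracle and the
survival-analysis implementation in lifelines. `r²m = r²·(1 − √|r²−r₀²|)`
uses the benchmark-lineage convention for r₀²: truth is regressed on
prediction through the origin (`k = Σyŷ/Σŷ²`) with residual variance
measured against the truth mean; the absolute value guards r₀² > r², a
case the formula otherwise leaves undefined. The convention is recorded in
the metrics report metadata. Davis dissociation constants load as
`pKd = −log₁₀(Kd/10⁹)` (the dense matrix pre-fills non-binders at
10,000 nM, i.e. pKd 5); KIBA scores load as distributed. Published KIBA
protein counts disagree between sources (229 vs 299); the loader reports
whatever the files contain and surfaces the discrepancy as a warning
rather than resolving it.

## Synthetic data

The generator emulates the input distributions the model consumes —
valid SMILES of 3–40 heavy atoms from an enumerated pool of alkanes,
alcohols, ethers, amines and aromatics; residue sequences of 30–1,200
letters drawn uniformly over the 21-symbol alphabet — with affinities
following a *known linear law*:

    raw = β₁·(heavy atoms)/10 + β₂·(fraction of A,V,L,I,F) + ε,  ε ~ N(0, σ)

affinely rescaled into [5, 11] to mimic pKd. β₁, β₂ ~ U(0.5, 1.5) are
drawn once per seed and the effective (post-rescaling) coefficients are
returned with the per-record descriptors, so ordinary least squares is a
closed-form recovery oracle and end-to-end learnability does not depend on
deep-net convergence luck. Defaults: 60 molecules, 80 proteins, noise SD
0.3 (≈5% of the label range).

What the generator does *not* emulate: real affinity distributions are
bimodal (Davis mass at pKd 5), molecules share scaffolds, protein
composition is non-uniform and sequence *order* carries signal. Passing
the synthetic tests therefore demonstrates that featurization, batching,
optimization, checkpointing and evaluation are correct and that the model
can extract composition-level signal — not that it reaches benchmark
accuracy on real data, which requires accelerator-scale training and is
out of scope here.

The cross-validated learning check uses a deliberately small
configuration (2D branch + 2-layer GCN, hidden/embed 32, one 64-unit FC
layer, mean pooling, `log1p`, 12 epochs at lr 2e-3, batch 64) chosen for
CPU minute-scale runtimes. Mean pooling is used there because the
molecular size signal survives averaging of degree/H-count one-hots
(e.g. the fraction of chain-end atoms is ≈ 2/n for alkanes), whereas max
pooling cannot distinguish chains longer than its receptive field;
problem sizes (n = 2000 records for the CV check, 100 for the ablation
wiring check) keep the whole suite at desk scale.

## Known limitations

- float64-on-CPU training is minutes-scale for thousands of records and
  impractical for the 100k-record benchmarks; the full-size configuration
  (`configs/benchmark.yaml`) is provided but expects accelerator-class
  reimplementation time budgets.
- The k-mer tensor is built in Python per sequence (~1 ms per 300
  residues); featurization caches unique molecules and proteins, which is
  what makes benchmark-shaped datasets (few proteins × many pairs)
  tractable.
- GAT attention uses the single-layer scorer formulation; no edge
  features, no multi-head averaging mode (concatenation only).
- No pretrained weights, hyperparameter search, or KIBA-score
  recomputation from raw Ki/Kd/IC50.
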