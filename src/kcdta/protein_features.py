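"""Protein sequence -> occurrence-matrix featurizations.

Two deterministic encodings of one amino-acid sequence over the 21-letter
alphabet ``P`` (L = 21):

* :func:`kmers_tensor` — an L x L x L tensor counting length-3 windows
  (step 1) by their *unordered* residue multiset, so every index permutation
  of a window's residues holds the same count and the tensor is fully
  symmetric in its three axes.
* :func:`cartesian_matrix` — an L x L matrix counting every *ordered* pair
  of sequence positions (the Cartesian product of the sequence with itself),
  which equals the outer product of the residue-composition vector with
  itself and so sums to ``len(sequence)**2``.

Both operate on raw integer counts; an optional ``log1p`` compression is
offered at the featurizer level because Cartesian counts grow quadratically
with sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .alphabet import ALPHABET_SIZE, encode_sequence, residue_counts

__all__ = [
    "KmerTensor",
    "PairMatrix",
    "kmers_tensor",
    "cartesian_matrix",
    "ProteinKmerFeaturizer",
    "ProteinCartesianFeaturizer",
]


@dataclass(frozen=True)
class KmerTensor:
    """21x21x21 unordered 3-mer occurrence counts for one sequence."""

    counts: np.ndarray
    source_length: int
    k: int = 3

    def __post_init__(self) -> None:
        expected = (ALPHABET_SIZE,) * self.k
        if self.counts.shape != expected:
            raise ValueError(f"counts must have shape {expected}")


@dataclass(frozen=True)
class PairMatrix:
    """21x21 ordered residue-pair occurrence counts for one sequence."""

    counts: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        if self.counts.shape != (ALPHABET_SIZE, ALPHABET_SIZE):
            raise ValueError("counts must be 21x21")


def kmers_tensor(sequence: str, k: int = 3) -> KmerTensor:
    """Count length-3 windows of ``sequence`` by unordered residue multiset.

    A window of length 3 slides with step 1; each window's sorted residue
    triple ``(i, j, l)`` increments the tensor at *every* permutation of
    ``(i, j, l)``, so e.g. the windows of ``"ACDAG"`` ({ACD, CDA, DAG})
    give count 2 at all six orderings of (A, C, D) and count 1 at all
    orderings of (A, D, G).  Sequences shorter than 3 yield the zero tensor.

    Only ``k=3`` is supported: the tensor dimensionality is ``21**k`` and
    other window sizes would change the downstream model's input shape.
    """
    if k != 3:
        raise ValueError(f"only k=3 is supported, got k={k}")
    idx = encode_sequence(sequence)
    n = idx.size
    counts = np.zeros((ALPHABET_SIZE,) * 3, dtype=np.int64)
    for start in range(n - k + 1):
        triple = tuple(sorted(idx[start : start + k]))
        for perm in set(permutations(triple)):
            counts[perm] += 1
    return KmerTensor(counts=counts, source_length=n, k=k)


def cartesian_matrix(sequence: str) -> PairMatrix:
    """Ordered residue-pair counts over all position pairs of ``sequence``.

    Every ordered pair of positions (p, q), including p == q, contributes
    one count at (residue(p), residue(q)).  Equivalently the matrix is the
    outer product of the residue-composition vector with itself; its total
    is ``len(sequence)**2``.
    """
    vec = residue_counts(sequence)
    counts = np.outer(vec, vec)
    return PairMatrix(counts=counts, source_length=int(vec.sum()))


class _BaseProteinFeaturizer:
    """Sklearn-style transformer turning sequences into count arrays.

    Parameters
    ----------
    log1p : bool
        Apply ``log(1 + c)`` to the counts.  Off by default (raw counts are
        the canonical output); useful for long sequences whose Cartesian
        counts span several orders of magnitude.
    """

    def __init__(self, log1p: bool = False):
        self.log1p = log1p

    def get_params(self, deep: bool = True) -> dict:
        return {"log1p": self.log1p}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def _encode_one(self, sequence: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        """Featurize an iterable of sequences into a stacked float array."""
        arrays = [self._encode_one(seq).astype(np.float64) for seq in X]
        out = np.stack(arrays)
        if self.log1p:
            out = np.log1p(out)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)


class ProteinKmerFeaturizer(_BaseProteinFeaturizer):
    """Transform sequences into (n, 21, 21, 21) 3-mer occurrence tensors."""

    def _encode_one(self, sequence: str) -> np.ndarray:
        return kmers_tensor(sequence).counts


class ProteinCartesianFeaturizer(_BaseProteinFeaturizer):
    """Transform sequences into (n, 21, 21) Cartesian pair matrices."""

    def _encode_one(self, sequence: str) -> np.ndarray:
        return cartesian_matrix(sequence).counts
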