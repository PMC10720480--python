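"""The 21-symbol residue alphabet shared by both protein featurizations.

The vocabulary covers the 20 standard amino acids plus ``X``, the wildcard
for unknown or non-standard residues.  Its order is fixed so that serialized
occurrence tensors are portable across machines: ``X`` sits between ``W``
and ``Y``.
"""

from __future__ import annotations

import numpy as np

#: Ordered residue vocabulary. Index 19 is the wildcard X.
RESIDUE_SYMBOLS: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L",
    "M", "N", "P", "Q", "R", "S", "T", "V", "W", "X", "Y",
)

#: Alphabet size (21).
ALPHABET_SIZE: int = len(RESIDUE_SYMBOLS)

_INDEX_OF: dict[str, int] = {s: i for i, s in enumerate(RESIDUE_SYMBOLS)}
_X_INDEX: int = _INDEX_OF["X"]


class ResidueAlphabet:
    """The ordered residue vocabulary and its symbol -> index map."""

    symbols = RESIDUE_SYMBOLS
    index_of = _INDEX_OF

    def __len__(self) -> int:  # pragma: no cover - trivial
        return ALPHABET_SIZE


def encode_residue(ch: str, position: int | None = None) -> int:
    """Map a single residue letter to its alphabet index in ``[0, 20]``.

    Letters outside the vocabulary (B, J, O, U, Z, ...) encode as ``X``;
    lower-case input is accepted.  Non-letter characters raise ``ValueError``.
    """
    if not isinstance(ch, str) or len(ch) != 1:
        raise ValueError(f"expected a single character, got {ch!r}")
    if not ch.isalpha():
        where = f" at position {position}" if position is not None else ""
        raise ValueError(f"non-letter residue character {ch!r}{where}")
    return _INDEX_OF.get(ch.upper(), _X_INDEX)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a residue string into an integer index array.

    Whitespace is stripped and case is ignored.  Raises ``ValueError`` on an
    empty sequence or any non-letter character (reported with its position).
    """
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise ValueError("empty protein sequence")
    idx = np.empty(len(seq), dtype=np.int64)
    for pos, ch in enumerate(seq):
        idx[pos] = encode_residue(ch, position=pos)
    return idx


def residue_counts(sequence: str) -> np.ndarray:
    """Length-21 residue composition vector of ``sequence``.

    The vector sums to the sequence length; unknown letters are tallied
    under ``X``.
    """
    idx = encode_sequence(sequence)
    return np.bincount(idx, minlength=ALPHABET_SIZE).astype(np.int64)
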