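"""SMILES -> atom/bond graph featurization for the GNN branch.

Heavy-atom-only graphs with the 78-dimensional one-hot atom feature scheme
used by the GraphDTA family of affinity models: element symbol (44 slots
with a trailing "other" bucket), degree (0-10), total hydrogen count (0-10),
implicit valence (0-10) and an aromaticity flag.  Each bond contributes two
directed edges; no edge attributes are stored (none of the message-passing
layers consume them) and no explicit self-loops (the GCN layer adds its own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = ["MoleculeGraph", "SmilesParseError", "atom_features", "smiles_to_graph",
           "MoleculeGraphFeaturizer", "ATOM_FEATURE_DIM"]

_ELEMENT_LIST = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
]
_RANGE_11 = list(range(11))

#: Width of one atom-feature row: 44 + 11 + 11 + 11 + 1.
ATOM_FEATURE_DIM = len(_ELEMENT_LIST) + 3 * len(_RANGE_11) + 1


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class MoleculeGraph:
    """Node-feature table plus bidirectional edge list for one molecule.

    ``node_features`` is (N, 78); ``edges`` is (2, E) with every chemical
    bond present in both directions.
    """

    node_features: np.ndarray
    edges: np.ndarray
    num_nodes: int

    def __post_init__(self) -> None:
        if self.num_nodes < 1:
            raise ValueError("a molecule graph needs at least one atom")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= self.num_nodes):
            raise ValueError("edge indices out of range")


def _one_hot(value, choices, clamp_last: bool) -> list[float]:
    if value not in choices:
        if not clamp_last:
            raise ValueError(f"{value!r} not in allowed set")
        value = choices[-1]
    return [1.0 if value == c else 0.0 for c in choices]


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """78-component one-hot feature vector for one RDKit atom.

    Blocks: element symbol (44, unknown -> last bucket), degree (11),
    total H count (11), implicit valence (11), aromatic flag (1).  Exactly
    one slot is hot per one-hot block, so each row sums to 4 or 5.
    """
    feats = (
        _one_hot(atom.GetSymbol(), _ELEMENT_LIST, clamp_last=True)
        + _one_hot(atom.GetDegree(), _RANGE_11, clamp_last=True)
        + _one_hot(atom.GetTotalNumHs(), _RANGE_11, clamp_last=True)
        + _one_hot(atom.GetImplicitValence(), _RANGE_11, clamp_last=True)
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.asarray(feats, dtype=np.float64)


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Hydrogens stay implicit (heavy atoms only); node order is RDKit's atom
    order for the parsed molecule; each bond is doubled into both directed
    edges.  Raises :class:`SmilesParseError` for chemically invalid input
    and ``ValueError`` for empty input or molecules with no heavy atoms.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError(f"molecule with zero heavy atoms: {smiles!r}")
    features = np.stack([atom_features(a) for a in mol.GetAtoms()])
    pairs: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        pairs.append((u, v))
        pairs.append((v, u))
    edges = (
        np.asarray(pairs, dtype=np.int64).T if pairs else np.zeros((2, 0), dtype=np.int64)
    )
    return MoleculeGraph(node_features=features, edges=edges, num_nodes=n)


class MoleculeGraphFeaturizer:
    """Transformer mapping SMILES strings to :class:`MoleculeGraph` objects."""

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[MoleculeGraph]:
        return [smiles_to_graph(s) for s in X]

    def fit_transform(self, X, y=None) -> list[MoleculeGraph]:
        return self.transform(X)
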