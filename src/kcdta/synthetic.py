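"""Download-free synthetic drug-target datasets with a known generative law.

Molecules come from an enumerated pool of valid SMILES (alkanes, alcohols,
ethers, amines and aromatics spanning 3-40 heavy atoms); protein sequences
are sampled uniformly over the 21-letter residue alphabet.  The affinity is
a *linear* function of two simple descriptors —

    raw = beta1 * (heavy-atom count) / 10
        + beta2 * (fraction of hydrophobic residues A, V, L, I, F)
        + Normal(0, noise_sd)

— affinely rescaled into the pKd-like range [5, 11].  Linearity guarantees
learnability and gives a closed-form recovery oracle (ordinary least
squares on the two true descriptors), so end-to-end training tests do not
hinge on deep-network convergence luck.  The effective (post-rescaling)
coefficients are returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .alphabet import RESIDUE_SYMBOLS
from .data_io import DTARecord

__all__ = ["SyntheticSpec", "generate_dataset", "molecule_pool",
           "heavy_atom_count", "hydrophobic_fraction"]

_HYDROPHOBIC = set("AVLIF")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_records: int = 1000
    n_molecules: int = 60
    n_proteins: int = 80
    seq_length_range: tuple[int, int] = (30, 1200)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_records, self.n_molecules, self.n_proteins) < 1:
            raise ValueError("n_records, n_molecules and n_proteins must be positive")
        lo, hi = self.seq_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid sequence length range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def molecule_pool() -> list[str]:
    """Enumerated pool of valid small-molecule SMILES, 3-40 heavy atoms."""
    pool: list[str] = []
    # linear alkanes and primary alcohols
    for n in range(3, 41, 2):
        pool.append("C" * n)
    for n in range(2, 36, 3):
        pool.append("C" * n + "O")
    # branched alkanes
    pool += ["CC(C)C", "CC(C)(C)C", "CC(C)CC", "CC(C)CC(C)C", "CC(C)(C)CC(C)(C)C",
             "CC(C)CCCC(C)C", "CC(CC(C)C)CC(C)C"]
    # ethers and amines
    pool += ["CCOCC", "CCCOCCC", "CCOCCOCC", "CCN", "CCCN", "CCNCC", "CCCNCCC",
             "CCOC(C)C", "CCCCOCCCC"]
    # aromatics and substituted rings
    pool += ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1", "CCCCCc1ccccc1",
             "Oc1ccccc1", "Nc1ccccc1", "COc1ccccc1", "Cc1ccc(C)cc1", "Cc1ccccc1C",
             "c1ccc2ccccc2c1", "Cc1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",
             "CCc1ccc(CC)cc1", "Oc1ccc(O)cc1", "c1ccc2c(c1)ccc1ccccc12",
             "CCCCCCc1ccccc1", "CCCCCCCCc1ccccc1", "Cc1cccc(C)c1",
             "OCc1ccccc1", "NCc1ccccc1", "CC(C)c1ccccc1", "CCOc1ccccc1"]
    validated = []
    for smi in pool:
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, smi
        assert 3 <= mol.GetNumAtoms() <= 40, smi
        validated.append(smi)
    return validated


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol.GetNumAtoms()


def hydrophobic_fraction(sequence: str) -> float:
    """Fraction of residues in {A, V, L, I, F}."""
    seq = sequence.upper()
    return sum(ch in _HYDROPHOBIC for ch in seq) / len(seq)


def generate_dataset(spec: SyntheticSpec) -> tuple[list[DTARecord], dict]:
    """Generate a seeded synthetic dataset plus its ground-truth parameters.

    Returns ``(records, truth)`` where ``truth`` holds the effective
    intercept and coefficients of the affine-rescaled generative law
    (``beta0``, ``beta_atoms`` on heavy-atom-count/10, ``beta_hydro`` on
    hydrophobic fraction), the rescaled ``noise_sd``, and the per-record
    descriptor matrix — everything an ordinary-least-squares oracle needs
    to verify recovery.
    """
    rng = np.random.default_rng(spec.seed)
    pool = molecule_pool()
    take = min(spec.n_molecules, len(pool))
    molecules = [str(s) for s in rng.choice(pool, size=take, replace=False)]
    atoms = np.array([heavy_atom_count(s) for s in molecules], dtype=np.float64)

    letters = np.array(list(RESIDUE_SYMBOLS))
    lo, hi = spec.seq_length_range
    sequences = []
    for _ in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        sequences.append("".join(rng.choice(letters, size=length)))
    hydro = np.array([hydrophobic_fraction(s) for s in sequences])

    beta1 = rng.uniform(0.5, 1.5)
    beta2 = rng.uniform(0.5, 1.5)

    n_pairs = len(molecules) * len(sequences)
    if spec.n_records <= n_pairs:
        flat = rng.choice(n_pairs, size=spec.n_records, replace=False)
    else:
        flat = rng.integers(0, n_pairs, size=spec.n_records)
    mol_idx, prot_idx = np.unravel_index(flat, (len(molecules), len(sequences)))

    d_atoms = atoms[mol_idx] / 10.0
    d_hydro = hydro[prot_idx]
    raw = beta1 * d_atoms + beta2 * d_hydro + rng.normal(0.0, spec.noise_sd,
                                                         size=spec.n_records)
    span = raw.max() - raw.min()
    scale = 6.0 / span if span > 0 else 1.0
    shift = 5.0 - scale * raw.min()
    affinity = shift + scale * raw

    records = [
        DTARecord(molecule_id=f"M{m:03d}", smiles=molecules[m],
                  protein_id=f"P{p:03d}", sequence=sequences[p],
                  affinity=float(a), source="synthetic")
        for m, p, a in zip(mol_idx, prot_idx, affinity)
    ]
    truth = {
        "beta0": float(shift),
        "beta_atoms": float(scale * beta1),
        "beta_hydro": float(scale * beta2),
        "noise_sd": float(scale * spec.noise_sd),
        "raw_betas": (float(beta1), float(beta2)),
        "descriptors": np.column_stack([d_atoms, d_hydro]),
    }
    return records, truth
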