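"""Benchmark loading, label transforms and split schemes.

Canonical record: one (SMILES, protein sequence, affinity) triple with
provenance.  Loaders cover the DeepDTA benchmark directory dialect
(insertion-ordered ligand/protein JSON maps plus a dense drug x protein
affinity matrix with missing entries and fold-index files), generic CSV
tables, and FASTA for sequences.  Sequences are never truncated.

Davis affinities are dissociation constants in nanomolar and are moved to
log space via ``pKd = -log10(Kd / 1e9)``; KIBA scores are used as
distributed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem

logger = logging.getLogger("kcdta")

__all__ = [
    "DTARecord", "SplitPlan", "pkd_transform", "load_deepdta_dataset",
    "load_csv_dataset", "save_csv_dataset", "load_fasta", "make_splits",
]


@dataclass(frozen=True)
class DTARecord:
    """One (molecule, protein, affinity) training example with provenance."""

    molecule_id: str
    smiles: str
    protein_id: str
    sequence: str
    affinity: float
    source: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("record with empty protein sequence")
        if not np.isfinite(self.affinity):
            raise ValueError("record with non-finite affinity")


@dataclass
class SplitPlan:
    """Index lists realizing one of the benchmark split schemes.

    ``deepdta_cv``: one held-out test part plus five cross-validation parts
    (train/val rotations are formed downstream).  ``random_ratio``: a
    seeded 4:1 train/test split.  ``temporal``: publication-year cutoffs
    (train <= 2011, validation == 2012, test >= 2013).
    """

    scheme: str
    seed: int
    cv_folds: list[np.ndarray] = field(default_factory=list)
    test_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    train_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    val_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def all_indices(self) -> np.ndarray:
        parts = [self.test_indices, self.train_indices, self.val_indices, *self.cv_folds]
        return np.sort(np.concatenate([np.asarray(p, dtype=np.int64) for p in parts]))


def pkd_transform(kd: float) -> float:
    """Convert a dissociation constant in nanomolar to pKd = -log10(Kd/1e9)."""
    kd = float(kd)
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    return float(-np.log10(kd / 1e9))


def _find_file(directory: Path, candidates: list[str]) -> Path:
    for name in candidates:
        path = directory / name
        if path.exists():
            return path
    raise FileNotFoundError(
        f"none of {candidates} found in {directory}")


def _load_json_map(path: Path) -> dict[str, str]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not hold a JSON object")
    return data


def _load_matrix(path: Path) -> np.ndarray:
    """Dense affinity matrix: pickled numpy (benchmark dialect) or text."""
    if path.suffix in {".txt", ".csv", ".tsv"}:
        try:
            delim = "," if path.suffix == ".csv" else None
            return np.loadtxt(path, delimiter=delim)
        except ValueError:
            pass  # fall through to pickle
    try:
        arr = np.load(path, allow_pickle=True, encoding="latin1")
    except (ValueError, OSError):
        import pickle

        with open(path, "rb") as fh:
            arr = pickle.load(fh, encoding="latin1")
    return np.asarray(arr, dtype=np.float64)


def load_deepdta_dataset(directory, name: str):
    """Load a DeepDTA-dialect benchmark directory.

    Returns ``(records, folds)`` where ``records`` has one entry per
    non-missing affinity-matrix cell in row-major order — the order the
    published fold-index files refer to — and ``folds`` is
    ``{"train": [five index lists], "test": index list}`` or ``None`` if
    no fold files are present.  ``name`` selects the label convention:
    ``davis`` passes raw nanomolar Kd through :func:`pkd_transform`,
    ``kiba`` keeps the distributed KIBA scores.
    """
    name = name.lower()
    if name not in {"davis", "kiba"}:
        raise ValueError(f"name must be 'davis' or 'kiba', got {name!r}")
    directory = Path(directory)
    ligand_path = _find_file(directory, ["ligands_can.txt", "ligands_iso.txt",
                                         "ligands.json", "ligands.txt"])
    protein_path = _find_file(directory, ["proteins.txt", "proteins.json"])
    matrix_path = _find_file(directory, ["Y", "Y.txt", "Y.csv", "Y.tsv",
                                         "affinities.txt"])
    ligands = _load_json_map(ligand_path)
    proteins = _load_json_map(protein_path)
    matrix = _load_matrix(matrix_path)
    if matrix.shape != (len(ligands), len(proteins)):
        raise ValueError(
            f"affinity matrix shape {matrix.shape} does not match "
            f"{len(ligands)} ligands x {len(proteins)} proteins")

    drug_ids, smiles = zip(*ligands.items())
    protein_ids, sequences = zip(*proteins.items())
    records: list[DTARecord] = []
    rows, cols = np.where(~np.isnan(matrix))  # row-major, the published fold order
    for r, c in zip(rows, cols):
        value = float(matrix[r, c])
        affinity = pkd_transform(value) if name == "davis" else value
        records.append(DTARecord(
            molecule_id=str(drug_ids[r]), smiles=smiles[r],
            protein_id=str(protein_ids[c]), sequence=sequences[c],
            affinity=affinity, source=name))

    folds = None
    try:
        train_path = _find_file(directory, ["folds/train_fold_setting1.txt",
                                            "train_fold_setting1.txt"])
        test_path = _find_file(directory, ["folds/test_fold_setting1.txt",
                                           "test_fold_setting1.txt"])
        with open(train_path) as fh:
            train_folds = json.load(fh)
        with open(test_path) as fh:
            test_fold = json.load(fh)
        folds = {"train": [np.asarray(f, dtype=np.int64) for f in train_folds],
                 "test": np.asarray(test_fold, dtype=np.int64)}
    except FileNotFoundError:
        pass

    logger.info("loaded %s: %d records, %d compounds, %d proteins",
                name, len(records), len(ligands), len(proteins))
    if name == "kiba":
        # published protein counts for KIBA disagree (229 in the dataset
        # description vs 299 in the benchmark summary table); report what
        # the files contain and leave the discrepancy visible.
        if len(proteins) not in (229, 299):
            logger.warning(
                "KIBA protein count is %d; published sources state 229 or 299",
                len(proteins))
    return records, folds


def load_csv_dataset(path, source: str | None = None) -> list[DTARecord]:
    """Load records from a CSV with smiles, sequence and affinity columns.

    Optional columns: ``molecule_id``, ``protein_id``, ``year``.  Rows
    whose SMILES fail to parse are dropped with a logged count.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty dataset file: {path}") from exc
    required = {"smiles", "sequence", "affinity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path} is missing required columns: {sorted(missing)}")
    records: list[DTARecord] = []
    n_bad = 0
    for i, row in frame.iterrows():
        if Chem.MolFromSmiles(str(row["smiles"])) is None:
            n_bad += 1
            continue
        records.append(DTARecord(
            molecule_id=str(row.get("molecule_id", f"mol{i}")),
            smiles=str(row["smiles"]),
            protein_id=str(row.get("protein_id", f"prot{i}")),
            sequence=str(row["sequence"]),
            affinity=float(row["affinity"]),
            source=source or path.stem,
            year=int(row["year"]) if "year" in frame.columns and pd.notna(row["year"]) else None,
        ))
    if n_bad:
        logger.warning("dropped %d rows with unparseable SMILES from %s", n_bad, path)
    logger.info("loaded %d records from %s", len(records), path)
    return records


def save_csv_dataset(records: list[DTARecord], path) -> None:
    """Write records to CSV so that :func:`load_csv_dataset` round-trips."""
    frame = pd.DataFrame({
        "molecule_id": [r.molecule_id for r in records],
        "smiles": [r.smiles for r in records],
        "protein_id": [r.protein_id for r in records],
        "sequence": [r.sequence for r in records],
        "affinity": [r.affinity for r in records],
    })
    years = [r.year for r in records]
    if any(y is not None for y in years):
        frame["year"] = years
    frame.to_csv(path, index=False)


def load_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA file into an id -> sequence map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def make_splits(records: list[DTARecord], scheme: str, seed: int = 0,
                published_folds: dict | None = None) -> SplitPlan:
    """Build a :class:`SplitPlan` under one of the benchmark protocols.

    ``deepdta_cv`` divides the records into six equal parts: one reserved
    as the test set and five cross-validation parts (published fold
    indices are used verbatim when given).  ``random_ratio`` is a seeded
    4:1 train/test split.  ``temporal`` assigns by publication year
    (<= 2011 train, == 2012 validation, >= 2013 test) and requires every
    record to carry a year.
    """
    n = len(records)
    if n == 0:
        raise ValueError("no records to split")
    if scheme == "deepdta_cv":
        if published_folds is not None:
            return SplitPlan(scheme=scheme, seed=seed,
                             cv_folds=[np.asarray(f, dtype=np.int64)
                                       for f in published_folds["train"]],
                             test_indices=np.asarray(published_folds["test"], dtype=np.int64))
        order = np.random.default_rng(seed).permutation(n)
        parts = np.array_split(order, 6)
        return SplitPlan(scheme=scheme, seed=seed,
                         cv_folds=[np.sort(p) for p in parts[1:]],
                         test_indices=np.sort(parts[0]))
    if scheme == "random_ratio":
        order = np.random.default_rng(seed).permutation(n)
        n_test = n // 5
        return SplitPlan(scheme=scheme, seed=seed,
                         test_indices=np.sort(order[:n_test]),
                         train_indices=np.sort(order[n_test:]))
    if scheme == "temporal":
        years = [r.year for r in records]
        if any(y is None for y in years):
            raise ValueError("temporal split requires a year on every record")
        years_arr = np.asarray(years)
        idx = np.arange(n)
        return SplitPlan(scheme=scheme, seed=seed,
                         train_indices=idx[years_arr <= 2011],
                         val_indices=idx[years_arr == 2012],
                         test_indices=idx[years_arr >= 2013])
    raise ValueError(f"unknown split scheme {scheme!r}")
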