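"""End-to-end orchestration: featurize -> split -> train -> evaluate.

Implements the benchmark cross-validation protocol: the dataset is divided
into six equal parts, one reserved as the held-out test set; the remaining
five rotate as validation sets, giving five training runs whose best
checkpoints are each evaluated on the same test part.  The summary reports
per-fold and mean (std) CI / MSE / r²m.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import DTARecord, make_splits
from .metrics import MetricsReport, evaluate_predictions
from .model import FeaturizedDataset, featurize_pairs, predict_affinity, train
from .network import KCDTANetwork, ModelConfig

logger = logging.getLogger("kcdta")

__all__ = ["RunConfig", "CrossValidationResult", "run_cross_validation",
           "predict_records", "write_run_log"]


@dataclass
class RunConfig:
    """Everything one training/evaluation run needs."""

    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 20
    lr: float = 5e-4
    batch_size: int = 128
    log1p: bool = False
    split_scheme: str = "deepdta_cv"
    seed: int = 0
    output_dir: str | None = None


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    summary: dict
    fold_seeds: list[int]
    histories: list


def _featurize_records(records: list[DTARecord], config: RunConfig) -> FeaturizedDataset:
    return featurize_pairs(
        [r.smiles for r in records], [r.sequence for r in records],
        y=[r.affinity for r in records],
        branches=config.model.protein_branches, log1p=config.log1p)


def run_cross_validation(records: list[DTARecord], config: RunConfig,
                         published_folds: dict | None = None) -> CrossValidationResult:
    """Run the six-part CV protocol and evaluate each fold on the test part.

    Fold ``i`` trains on four cross-validation parts with the fifth as the
    validation set used for best-checkpoint selection; the returned
    checkpoint is scored on the fixed test part.  Per-fold model seeds are
    ``config.seed + fold`` and are logged.
    """
    plan = make_splits(records, "deepdta_cv", seed=config.seed,
                       published_folds=published_folds)
    data = _featurize_records(records, config)
    test_data = data.subset(plan.test_indices)
    reports: list[MetricsReport] = []
    histories = []
    fold_seeds = []
    for fold in range(len(plan.cv_folds)):
        val_idx = plan.cv_folds[fold]
        train_idx = np.concatenate(
            [plan.cv_folds[j] for j in range(len(plan.cv_folds)) if j != fold])
        fold_seed = config.seed + fold
        fold_seeds.append(fold_seed)
        model_config = ModelConfig(**{**config.model.to_dict(), "seed": fold_seed})
        network = KCDTANetwork(model_config)
        logger.info("fold %d: %d train / %d val / %d test records (seed %d)",
                    fold, train_idx.size, val_idx.size, plan.test_indices.size,
                    fold_seed)
        try:
            network, history = train(
                network, data.subset(train_idx), data.subset(val_idx),
                lr=config.lr, batch_size=config.batch_size,
                epochs=config.epochs, seed=fold_seed)
        except Exception as exc:
            raise RuntimeError(f"cross-validation fold {fold} failed: {exc}") from exc
        pred = predict_affinity(network, test_data)
        reports.append(evaluate_predictions(test_data.y, pred))
        histories.append(history)
    summary = _summarize(reports)
    return CrossValidationResult(fold_reports=reports, summary=summary,
                                 fold_seeds=fold_seeds, histories=histories)


def _summarize(reports: list[MetricsReport]) -> dict:
    summary = {}
    for name in ("ci", "mse", "rmse", "rm2"):
        values = np.array([getattr(r, name) for r in reports])
        summary[f"{name}_mean"] = float(values.mean())
        summary[f"{name}_std"] = float(values.std())
    summary["n_folds"] = len(reports)
    return summary


def predict_records(network: KCDTANetwork, records: list[DTARecord],
                    log1p: bool = False, batch_size: int = 256) -> np.ndarray:
    """Predict affinities for already-validated records."""
    data = featurize_pairs(
        [r.smiles for r in records], [r.sequence for r in records],
        branches=network.config.protein_branches, log1p=log1p)
    return predict_affinity(network, data, batch_size=batch_size)


def write_run_log(path, config: RunConfig, extra: dict | None = None) -> None:
    """Write a machine-readable log of config, seeds and library versions."""
    import numpy
    import pandas
    import rdkit
    import sklearn

    payload = {
        "config": {
            "model": config.model.to_dict(),
            "epochs": config.epochs,
            "lr": config.lr,
            "batch_size": config.batch_size,
            "log1p": config.log1p,
            "split_scheme": config.split_scheme,
            "seed": config.seed,
        },
        "versions": {
            "python": sys.version,
            "platform": platform.platform(),
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "rdkit": rdkit.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
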