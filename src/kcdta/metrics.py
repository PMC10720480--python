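"""Evaluation metrics for affinity regression: CI, MSE/RMSE and r²m.

The concordance index (CI) is the probability that a randomly chosen pair
of examples with distinct true affinities is ranked correctly by the
predictions; prediction ties score 0.5.  r²m is the external-validation
QSAR statistic ``r² · (1 − sqrt(|r² − r₀²|))`` where r² is the squared
Pearson correlation and r₀² the coefficient of determination of the
through-origin regression of truth on prediction (the convention of the
DeepDTA benchmark lineage, recorded in the report metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "MetricsReport",
    "concordance_index",
    "mse",
    "rmse",
    "rm_squared",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class MetricsReport:
    ci: float
    mse: float
    rmse: float
    rm2: float
    n_pairs_compared: int
    metadata: dict = field(default_factory=lambda: {"r0_convention": "truth_on_pred_through_origin"})

    def to_dict(self) -> dict:
        return asdict(self)


def _as_vectors(truth, pred, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=np.float64).ravel()
    p = np.asarray(pred, dtype=np.float64).ravel()
    if t.size != p.size:
        raise ValueError(f"length mismatch: truth has {t.size}, pred has {p.size}")
    if t.size < min_len:
        raise ValueError(f"need at least {min_len} observations, got {t.size}")
    return t, p


def concordance_index(truth, pred) -> float:
    """CI over all pairs with distinct true values.

    For each pair ordered so the true affinity is larger for the first
    element, the pair scores 1 if the predictions agree in order, 0.5 if
    they tie, 0 otherwise; CI is the mean score.  Pairs with tied truth are
    not comparable and are excluded from the denominator.
    """
    t, p = _as_vectors(truth, pred, min_len=2)
    dt = t[:, None] - t[None, :]
    comparable = dt > 0  # ordered pairs (i, j) with t_i > t_j
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("undefined CI: all truth values are equal")
    dp = p[:, None] - p[None, :]
    scores = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(scores[comparable].sum() / n_pairs)


def n_comparable_pairs(truth) -> int:
    """Number of ordered pairs with distinct truth values (CI denominator)."""
    t = np.asarray(truth, dtype=np.float64).ravel()
    return int((t[:, None] > t[None, :]).sum())


def mse(truth, pred) -> float:
    """Mean squared difference between truth and prediction."""
    t, p = _as_vectors(truth, pred)
    return float(np.mean((t - p) ** 2))


def rmse(truth, pred) -> float:
    """Square root of the mean squared error."""
    return float(np.sqrt(mse(truth, pred)))


def rm_squared(truth, pred) -> float:
    """Modified squared correlation r²m = r²·(1 − sqrt(|r² − r₀²|)).

    r² is the squared Pearson correlation of truth and prediction; r₀² is
    the determination coefficient of the through-origin regression of truth
    on prediction (slope ``k = Σ y·ŷ / Σ ŷ²``, residual variance measured
    against the mean of truth).  The absolute value guards the r₀² > r²
    corner; r²m ≤ r² always.
    """
    t, p = _as_vectors(truth, pred, min_len=3)
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        raise ValueError("undefined r2m: constant truth or prediction vector")
    r = np.corrcoef(t, p)[0, 1]
    r2 = r * r
    k = float(np.sum(t * p) / np.sum(p * p))
    ss_res = float(np.sum((t - k * p) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r02))))


def evaluate_predictions(truth, pred) -> MetricsReport:
    """Compute the full metric suite for one prediction vector."""
    t, p = _as_vectors(truth, pred, min_len=2)
    return MetricsReport(
        ci=concordance_index(t, p),
        mse=mse(t, p),
        rmse=rmse(t, p),
        rm2=rm_squared(t, p),
        n_pairs_compared=n_comparable_pairs(t),
    )
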