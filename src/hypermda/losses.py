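"""Training losses and evaluation metrics.

The model trains with a Sorensen-Dice overlap loss on the sigmoid outputs:

    L = 1 - (X + eps) / (U - X + eps),
    X = sum_i t_i q_i,    U = sum_i (t_i^2 + q_i^2),

where q_i in (0, 1) is a predicted probability, t_i in {0, 1} a label and
eps a smoothing factor.  Note the denominator U - X: this is the
soft-Jaccard (intersection-over-union) form, though the loss travels under
the Sorensen-Dice name in this literature; it is implemented here as
printed, with the classic Dice form 1 - (2X + eps)/(U + eps) available via
``form="classic_dice"``.  Binary cross-entropy is provided for the
loss-function ablation.

Metrics (AUC, AUPRC, accuracy, F1, precision, recall) are computed with
scikit-learn; AUC is the probability that a random positive outranks a
random negative with ties credited 0.5, AUPRC is the precision-recall step
integral (average precision).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm

from .fusion import PairScore

__all__ = [
    "EvaluationReport",
    "dice_loss",
    "dice_loss_grad",
    "bce_loss",
    "compute_metrics",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 1.0


@dataclass
class EvaluationReport:
    """Fold- or run-level evaluation summary; all metric values in [0, 1]."""

    auc: float
    auprc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    threshold: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return asdict(self)


def _check_inputs(q, t, epsilon):
    q = np.asarray(q, dtype=np.float64).ravel()
    t = np.asarray(t, dtype=np.float64).ravel()
    if q.size != t.size or q.size == 0:
        raise ValueError("predictions and targets must be equal-length and non-empty")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError("predictions must lie strictly inside (0, 1)")
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("targets must be 0 or 1")
    return q, t


def dice_loss(q, t, epsilon: float = DEFAULT_EPSILON, form: str = "as_printed") -> float:
    """Sorensen-Dice overlap loss of predictions `q` against labels `t`.

    ``form="as_printed"`` uses the soft-Jaccard denominator U - X + eps;
    ``form="classic_dice"`` uses 1 - (2X + eps)/(U + eps).
    """
    q, t = _check_inputs(q, t, epsilon)
    X = float(np.dot(t, q))
    U = float(np.dot(t, t) + np.dot(q, q))
    if form == "as_printed":
        return 1.0 - (X + epsilon) / (U - X + epsilon)
    if form == "classic_dice":
        return 1.0 - (2.0 * X + epsilon) / (U + epsilon)
    raise ValueError(f"unknown loss form {form!r}")


def dice_loss_grad(q, t, epsilon: float = DEFAULT_EPSILON,
                   form: str = "as_printed") -> np.ndarray:
    """Analytic gradient of :func:`dice_loss` with respect to `q`."""
    q, t = _check_inputs(q, t, epsilon)
    X = np.dot(t, q)
    U = np.dot(t, t) + np.dot(q, q)
    if form == "as_printed":
        denom = U - X + epsilon
        # L = 1 - (X+eps)/denom; dX/dq = t, dU/dq = 2q
        return (-(t * denom) + (X + epsilon) * (2.0 * q - t)) / denom**2
    if form == "classic_dice":
        denom = U + epsilon
        return (-(2.0 * t) * denom + (2.0 * X + epsilon) * 2.0 * q) / denom**2
    raise ValueError(f"unknown loss form {form!r}")


def bce_loss(q, t) -> float:
    """Mean binary cross-entropy, the ablation comparator loss."""
    q, t = _check_inputs(q, t, 1.0)
    return float(-np.mean(t * np.log(q) + (1.0 - t) * np.log(1.0 - q)))


def compute_metrics(scores, labels, threshold: float = 0.5) -> EvaluationReport:
    """Evaluate ranked pair scores against binary labels.

    `scores` may be a list of :class:`~hypermda.fusion.PairScore` or a plain
    numeric sequence.  Both classes must be present, otherwise AUC and AUPRC
    are undefined and a ``ValueError`` is raised.
    """
    if len(scores) and isinstance(scores[0], PairScore):
        s = np.array([p.probability for p in scores])
    else:
        s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.intp)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC/AUPRC")
    pred = (s >= threshold).astype(int)
    return EvaluationReport(
        auc=float(_skm.roc_auc_score(y, s)),
        auprc=float(_skm.average_precision_score(y, s)),
        accuracy=float(_skm.accuracy_score(y, pred)),
        f1=float(_skm.f1_score(y, pred, zero_division=0)),
        precision=float(_skm.precision_score(y, pred, zero_division=0)),
        recall=float(_skm.recall_score(y, pred, zero_division=0)),
        threshold=float(threshold),
        n_pos=n_pos,
        n_neg=n_neg,
    )
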