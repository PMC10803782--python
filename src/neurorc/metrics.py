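"""Performance metrics: classification scores, regression scores, memory capacity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score, f1_score, r2_score

from .errors import DegenerateInputError, ShapeError


@dataclass
class Score:
    name: str
    value: float
    n_samples: int
    extras: dict = field(default_factory=dict)


def _check_aligned(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ShapeError("true and predicted lengths differ")
    return a, b


def balanced_accuracy(true_labels, pred_labels) -> Score:
    """Mean per-class recall over the classes present in the truth."""
    y, p = _check_aligned(true_labels, pred_labels)
    classes = np.unique(y)
    recalls = {}
    for c in classes:
        sel = y == c
        recalls[int(c)] = float(np.mean(p[sel] == c))
    value = float(np.mean(list(recalls.values())))
    return Score("balanced_accuracy", value, len(y), {"per_class_recall": recalls})


def f1(true_labels, pred_labels, average: str = "binary") -> Score:
    """Harmonic mean of precision and recall; macro-averages over classes on request."""
    y, p = _check_aligned(true_labels, pred_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division classes score 0 by convention
        if average == "binary":
            pos = int(np.max(np.unique(y)))
            value = f1_score(y, p, pos_label=pos, average="binary", zero_division=0)
        elif average == "macro":
            value = f1_score(y, p, average="macro", zero_division=0)
        else:
            raise ShapeError(f"unknown F1 average {average!r}")
    return Score("f1", float(value), len(y))


def memory_capacity(true_targets: np.ndarray, preds: np.ndarray) -> Score:
    """MC = sum over lags of the squared Pearson correlation corr(y_k, yhat_k)^2.

    Lags whose prediction has zero variance contribute 0 (with a warning).
    The per-lag curve is stored in ``extras['per_lag']``.
    """
    Y, P = _check_aligned(true_targets, preds)
    Y = np.atleast_2d(Y.T).T
    P = np.atleast_2d(P.T).T
    if Y.shape != P.shape:
        raise ShapeError("true and predicted target shapes differ")
    K = Y.shape[1]
    per_lag = np.zeros(K)
    for k in range(K):
        if np.std(Y[:, k]) == 0:
            raise DegenerateInputError(f"target lag {k + 1} has zero variance")
        if np.std(P[:, k]) == 0:
            warnings.warn(f"zero-variance prediction at lag {k + 1}; contributes 0")
            continue
        r = np.corrcoef(Y[:, k], P[:, k])[0, 1]
        per_lag[k] = r * r
    return Score("memory_capacity", float(per_lag.sum()), Y.shape[0],
                 {"per_lag": per_lag, "mean_lag_corr_sq": float(per_lag.mean())})


def r_squared(true, pred) -> Score:
    """Coefficient of determination."""
    y, p = _check_aligned(true, pred)
    if np.std(y) == 0:
        raise DegenerateInputError("true values have zero variance; R^2 undefined")
    return Score("r_squared", float(r2_score(y, p)), len(y))


def corrcoef(true, pred) -> Score:
    """Pearson correlation coefficient."""
    y, p = _check_aligned(true, pred)
    if np.std(y) == 0 or np.std(p) == 0:
        raise DegenerateInputError("zero-variance input; correlation undefined")
    return Score("corrcoef", float(np.corrcoef(y, p)[0, 1]), len(y))
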