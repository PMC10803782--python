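"""Regularized linear readouts from reservoir states to task targets.

The readout is the only trained component of the pipeline. Features are
z-scored with training-set statistics and fitted with ridge regression
(unpenalized intercept). Classification uses ridge-on-labels: targets are
encoded as +/-1 (one-vs-rest for more than two classes) and decisions taken
by sign/argmax of the decision values -- i.e. the classical "Ridge
classifier".
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge

from .errors import DegenerateLabelError, ParameterError, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class ReadoutModel:
    """Fitted linear map from z-scored readout features to targets.

    ``coef`` is K x m (targets/classes by features) and ``intercept`` length
    K; :meth:`coefficients` appends the intercept as a final column.
    """

    coef: np.ndarray
    intercept: np.ndarray
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    mode: str
    regularization: float
    label_set: list[int] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return np.hstack([self.coef, self.intercept[:, None]])

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "mode": self.mode,
            "regularization": self.regularization,
            "label_set": self.label_set,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReadoutModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_std=np.asarray(d["scaler_std"], dtype=float),
            mode=d["mode"],
            regularization=d["regularization"],
            label_set=d["label_set"],
            meta=d.get("meta", {}),
        )


def _ridge_fit(X: np.ndarray, Y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Ridge with unpenalized intercept; lambda = 0 falls back to pseudoinverse."""
    if lam == 0.0:
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])
        if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            warnings.warn("rank-deficient design with lambda=0; using pseudoinverse")
        beta, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
        return beta[:-1].T, beta[-1].reshape(-1)
    model = Ridge(alpha=lam, fit_intercept=True)
    model.fit(X, Y)
    coef = np.atleast_2d(model.coef_)
    intercept = np.atleast_1d(model.intercept_)
    return coef, intercept


def fit_readout(
    states: np.ndarray,
    targets: np.ndarray,
    mode: str = "classification",
    regularization: float = 1.0,
) -> ReadoutModel:
    """Train a ridge readout on (already masked) state rows.

    For classification, ``targets`` is a 1-D integer label vector; binary
    problems are encoded as a single +/-1 column, multiclass as one-vs-rest
    columns. For regression, ``targets`` may be 1-D or T x K.
    """
    X = np.asarray(states, dtype=float)
    if X.ndim != 2:
        raise ShapeError("states must be a 2-D samples x features matrix")
    if regularization < 0:
        raise ParameterError("regularization must be non-negative")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std

    if mode == "regression":
        Y = np.asarray(targets, dtype=float)
        squeeze = Y.ndim == 1
        Y2 = Y[:, None] if squeeze else Y
        if Y2.shape[0] != X.shape[0]:
            raise ShapeError("states and targets row counts differ")
        coef, intercept = _ridge_fit(Xs, Y2, regularization)
        return ReadoutModel(coef, intercept, mean, std, "regression", regularization,
                            meta={"squeeze_output": squeeze})
    if mode == "classification":
        y = np.asarray(targets).ravel().astype(int)
        if y.shape[0] != X.shape[0]:
            raise ShapeError("states and targets row counts differ")
        labels = sorted(np.unique(y).tolist())
        if len(labels) < 2:
            raise DegenerateLabelError(
                f"classification needs >= 2 classes, got {labels}"
            )
        if len(labels) == 2:
            Y = np.where(y == labels[1], 1.0, -1.0)[:, None]
        else:
            Y = np.full((y.shape[0], len(labels)), -1.0)
            for k, lab in enumerate(labels):
                Y[y == lab, k] = 1.0
        coef, intercept = _ridge_fit(Xs, Y, regularization)
        return ReadoutModel(coef, intercept, mean, std, "classification",
                            regularization, label_set=labels)
    raise ParameterError(f"unknown readout mode {mode!r}")


def predict(m: ReadoutModel, states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and raw decision values for a state matrix.

    Regression returns (predictions, predictions). Binary classification
    returns labels from the sign of the single decision column (ties go to
    the lower label); multiclass takes the argmax over one-vs-rest columns.
    """
    X = np.asarray(states, dtype=float)
    if X.ndim != 2 or X.shape[1] != m.n_features:
        raise ShapeError(
            f"expected {m.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    Xs = (X - m.scaler_mean) / m.scaler_std
    dv = Xs @ m.coef.T + m.intercept
    if m.mode == "regression":
        out = dv[:, 0] if m.meta.get("squeeze_output") else dv
        return out, out
    assert m.label_set is not None
    if len(m.label_set) == 2:
        d = dv[:, 0]
        pred = np.where(d > 0, m.label_set[1], m.label_set[0])
        return pred, d
    idx = np.argmax(dv, axis=1)
    pred = np.asarray(m.label_set)[idx]
    return pred, dv


def majority_vote(labels: np.ndarray, groups: Sequence[Sequence[int]]) -> np.ndarray:
    """Per-group majority label over per-timestep predictions.

    ``groups`` holds, for each trial, the positions (into ``labels``) of its
    decision-epoch timesteps. Ties resolve to the lower label (logged).
    """
    labels = np.asarray(labels)
    out = np.empty(len(groups), dtype=labels.dtype)
    for g, rows in enumerate(groups):
        vals, counts = np.unique(labels[list(rows)], return_counts=True)
        winners = vals[counts == counts.max()]
        if winners.size > 1:
            logger.info("majority-vote tie in trial %d; taking lower label", g)
        out[g] = winners.min()
    return out
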