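"""Backpropagation pixel classifier for multiband cover mapping.

A deliberately classical one-hidden-layer perceptron: logistic activations
in both layers, full-batch gradient descent on squared error, RMS error
tracked per iteration, and training stopped at a target RMS (default 0.04)
or an iteration cap. This mirrors the network remote-sensing packages have
long shipped for supervised land-cover classification, rather than a
modern softmax/cross-entropy MLP.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, trailing-underscore fitted attributes)
and composes with sklearn model selection. Features are min-max scaled to
[0, 1] internally, using constants computed from the training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, DataError
from .grid import CATEGORICAL, CONTINUOUS, Grid
from .spectral import SceneStack


@dataclass
class TrainConfig:
    """Training-loop settings for the backprop classifier."""

    hidden_dim: int = 8
    learning_rate: float = 0.20
    momentum: float = 0.9
    max_iterations: int = 4000
    target_rms: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.target_rms <= 0:
            raise ConfigError("target_rms must be positive")
        if self.hidden_dim < 1:
            raise ConfigError("hidden_dim must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigError("momentum must be in [0, 1)")


def minmax_constants(X: np.ndarray, feature_names: list[str] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature minima and maxima; rejects constant (degenerate) features."""
    X = np.asarray(X, dtype=float)
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    degenerate = np.nonzero(mins == maxs)[0]
    if degenerate.size:
        names = ([feature_names[i] for i in degenerate] if feature_names
                 else degenerate.tolist())
        raise DataError(f"constant training feature(s): {names}")
    return mins, maxs


def normalize_features(stack: SceneStack, samples: pd.DataFrame,
                       class_names: tuple[str, ...]
                       ) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Feature matrix, one-hot targets and scaling constants for sampled cells.

    ``samples`` must carry ``row``, ``col`` and ``true_class`` columns and
    lie on the stack grid with no nodata at sampled cells.
    """
    rows = samples["row"].to_numpy()
    cols = samples["col"].to_numpy()
    nr, nc = stack.shape
    if (rows < 0).any() or (rows >= nr).any() or (cols < 0).any() or (cols >= nc).any():
        raise DataError("sample indices fall outside the stack grid")
    bad = stack.nodata_any()[rows, cols]
    if bad.any():
        raise DataError(f"nodata at sampled cells, rows {np.nonzero(bad)[0].tolist()}")
    X = stack.features_at(rows, cols)
    mins, maxs = minmax_constants(X, list(stack.feature_names))
    X01 = (X - mins) / (maxs - mins)
    codes = np.array([class_names.index(c) for c in samples["true_class"]])
    Y = np.eye(len(class_names))[codes]
    return X01, Y, (mins, maxs)


class BackpropPixelClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer backprop network with logistic activations.

    Parameters
    ----------
    hidden_dim : int
        Width of the single hidden layer.
    learning_rate : float
        Full-batch gradient-descent step on the mean squared error.
    momentum : float
        Classical momentum on the weight updates; 0 disables it.
    max_iterations : int
        Iteration cap.
    target_rms : float
        Stop as soon as the training RMS error drops to this level.
    random_state : int
        Seeds the uniform(-0.5, 0.5) weight initialization.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in training order.
    W1_, b1_, W2_, b2_ : ndarray
        Layer weights and biases.
    feature_mins_, feature_maxs_ : ndarray
        Min-max scaling constants from the training rows.
    rms_trace_ : list of float
        RMS error after each iteration; non-empty, final <= first.
    n_iter_ : int
    """

    def __init__(self, hidden_dim: int = 8, learning_rate: float = 0.20,
                 momentum: float = 0.9, max_iterations: int = 4000,
                 target_rms: float = 0.04, random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_iterations = max_iterations
        self.target_rms = target_rms
        self.random_state = random_state

    # -- core ------------------------------------------------------------

    def fit(self, X, y):
        cfg = TrainConfig(hidden_dim=self.hidden_dim, learning_rate=self.learning_rate,
                          momentum=self.momentum, max_iterations=self.max_iterations,
                          target_rms=self.target_rms, seed=self.random_state)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise DataError("X must be 2-D")
        if X.shape[0] == 0:
            raise DataError("empty training set")
        if X.shape[0] != y.shape[0]:
            raise DataError("X and y length mismatch")
        self.classes_, codes = np.unique(y, return_inverse=True)
        q = len(self.classes_)
        Y = np.eye(q)[codes]

        self.feature_mins_, self.feature_maxs_ = minmax_constants(X)
        Xn = (X - self.feature_mins_) / (self.feature_maxs_ - self.feature_mins_)
        n, d = Xn.shape
        self.n_features_in_ = d

        rng = np.random.default_rng(cfg.seed)
        W1 = rng.uniform(-0.5, 0.5, size=(d, cfg.hidden_dim))
        b1 = rng.uniform(-0.5, 0.5, size=cfg.hidden_dim)
        W2 = rng.uniform(-0.5, 0.5, size=(cfg.hidden_dim, q))
        b2 = rng.uniform(-0.5, 0.5, size=q)

        lr = cfg.learning_rate
        mom = cfg.momentum
        vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
        trace: list[float] = []
        for it in range(cfg.max_iterations):
            H = expit(Xn @ W1 + b1)
            O = expit(H @ W2 + b2)
            err = O - Y
            rms = float(np.sqrt(np.mean(err**2)))
            trace.append(rms)
            if rms <= cfg.target_rms:
                break
            delta_o = err * O * (1 - O)              # dE/dpreact, E = mean sq err
            delta_h = (delta_o @ W2.T) * H * (1 - H)
            vW2 = mom * vW2 - lr * (H.T @ delta_o) / n
            vb2 = mom * vb2 - lr * delta_o.mean(axis=0)
            vW1 = mom * vW1 - lr * (Xn.T @ delta_h) / n
            vb1 = mom * vb1 - lr * delta_h.mean(axis=0)
            W2 += vW2; b2 += vb2; W1 += vW1; b1 += vb1

        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        self.rms_trace_ = trace
        self.n_iter_ = len(trace)
        return self

    def _forward(self, X: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(X, dtype=float) - self.feature_mins_) / (
            self.feature_maxs_ - self.feature_mins_)
        H = expit(Xn @ self.W1_ + self.b1_)
        return expit(H @ self.W2_ + self.b2_)

    def decision_function(self, X):
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}")
        return self._forward(X)

    def predict_proba(self, X):
        """Output activations normalized to sum to one per sample."""
        act = self.decision_function(X)
        return act / act.sum(axis=1, keepdims=True)

    def predict(self, X):
        act = self.decision_function(X)
        return self.classes_[np.argmax(act, axis=1)]  # argmax: first (lowest) index wins ties

    # -- persistence -----------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        check_is_fitted(self, "W1_")
        payload = {
            "params": self.get_params(),
            "classes": np.asarray(self.classes_).tolist(),
            "W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(), "b2": self.b2_.tolist(),
            "feature_mins": self.feature_mins_.tolist(),
            "feature_maxs": self.feature_maxs_.tolist(),
            "rms_trace": self.rms_trace_,
            "n_iter": self.n_iter_,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BackpropPixelClassifier":
        payload = json.loads(Path(path).read_text())
        model = cls(**payload["params"])
        model.classes_ = np.asarray(payload["classes"])
        model.W1_ = np.asarray(payload["W1"])
        model.b1_ = np.asarray(payload["b1"])
        model.W2_ = np.asarray(payload["W2"])
        model.b2_ = np.asarray(payload["b2"])
        model.feature_mins_ = np.asarray(payload["feature_mins"])
        model.feature_maxs_ = np.asarray(payload["feature_maxs"])
        model.rms_trace_ = payload["rms_trace"]
        model.n_iter_ = payload["n_iter"]
        model.n_features_in_ = model.W1_.shape[0]
        return model


def train_bpnn(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
               ) -> BackpropPixelClassifier:
    """Functional wrapper over :class:`BackpropPixelClassifier`."""
    cfg = config or TrainConfig()
    model = BackpropPixelClassifier(
        hidden_dim=cfg.hidden_dim, learning_rate=cfg.learning_rate,
        max_iterations=cfg.max_iterations, target_rms=cfg.target_rms,
        random_state=cfg.seed)
    return model.fit(X, y)


def predict_map(model: BackpropPixelClassifier, stack: SceneStack
                ) -> tuple[Grid, Grid]:
    """Classify every valid cell of a stack.

    Returns a categorical class-code grid (codes index ``model.classes_``)
    and a continuous grid holding the winning class's normalized activation
    share. Nodata in any feature propagates to both outputs.
    """
    check_is_fitted(model, "W1_")
    if stack.n_features != model.n_features_in_:
        raise DataError(
            f"stack has {stack.n_features} features, model expects {model.n_features_in_}")
    mask = stack.nodata_any()
    X = stack.as_matrix()
    valid = ~mask.ravel()
    codes = np.zeros(X.shape[0], dtype=int)
    share = np.zeros(X.shape[0], dtype=float)
    if valid.any():
        proba = model.predict_proba(X[valid])
        codes[valid] = np.argmax(proba, axis=1)
        share[valid] = proba.max(axis=1)
    rows, cols = stack.shape
    cell = next(iter(stack.bands.values())).cell_size
    class_grid = Grid(values=codes.reshape(rows, cols), cell_size=cell,
                      nodata_mask=mask.copy(), kind=CATEGORICAL)
    prob_grid = Grid(values=share.reshape(rows, cols), cell_size=cell,
                     nodata_mask=mask.copy(), kind=CONTINUOUS)
    return class_grid, prob_grid
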