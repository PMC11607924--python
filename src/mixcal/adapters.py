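"""nu-SVR and single-hidden-layer ANN regressors behind the common surface.

These two models complete the four-way comparison (PLS, GBT, SVR, ANN).
Their internals are not the point of this package, so the SVR delegates to
scikit-learn's NuSVR (RBF kernel); the ANN is a deliberately small NumPy
feed-forward network trained by full-batch backpropagation because the
calibration needs per-epoch loss traces, a monitor set with patience-based
early stopping, and bit-reproducible seeded runs.

Both adapters expose ``predict`` like the PLS and GBT models, so the
evaluation pipeline is model-agnostic.  Hyperparameter presets per analyte
ship in ``data/presets.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.svm import NuSVR

from .latent import ScoreMatrix


@dataclass(frozen=True)
class SVRConfig:
    """nu-SVR with an RBF kernel: cost C, support-vector bound nu, width gamma."""

    C: float = 1.0
    nu: float = 0.5
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class SVRModel:
    estimator: NuSVR

    def predict(self, X) -> np.ndarray:
        Xm = np.atleast_2d(np.asarray(getattr(X, "scores", X), dtype=float))
        return self.estimator.predict(Xm)


def svr_fit(features, y, cfg: SVRConfig = SVRConfig()) -> SVRModel:
    """Train nu-SVR with an RBF kernel on the features as given.

    No internal rescaling: gamma acts on raw (preprocessed/compressed)
    feature distances, matching how chemometrics toolboxes apply SVR to
    already-preprocessed absorbance matrices — the stated gamma presets
    only make sense on that scale.  The QP solver is deterministic, so
    refits reproduce predictions; constant y is rejected.
    """
    X = np.atleast_2d(np.asarray(getattr(features, "scores", features), dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and y must be finite")
    if np.std(y) == 0:
        raise ValueError("y is constant; SVR target is degenerate")
    est = NuSVR(C=cfg.C, nu=cfg.nu, gamma=cfg.gamma, kernel="rbf", tol=1e-6)
    est.fit(X, y)
    return SVRModel(est)


@dataclass(frozen=True)
class ANNConfig:
    """Single-hidden-layer feed-forward net trained by backpropagation.

    ``learning_rate`` defaults to 0.125 (full-batch gradient step on the
    standardised problem); early stopping watches a monitor set's RMSE and
    stops once it has risen for ``patience`` + 1 consecutive epochs,
    restoring the best weights seen.
    """

    hidden: int = 5
    learning_rate: float = 0.125
    max_epochs: int = 2000
    patience: int = 20
    activation: str = "tanh"  # or "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden < 1:
            raise ValueError("hidden layer size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.activation not in ("tanh", "sigmoid"):
            raise ValueError("activation must be 'tanh' or 'sigmoid'")


def _act(z: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "tanh":
        a = np.tanh(z)
        return a, 1.0 - a * a
    a = 1.0 / (1.0 + np.exp(-z))
    return a, a * (1.0 - a)


@dataclass
class ANNModel:
    config: ANNConfig
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    train_trace: np.ndarray
    monitor_trace: np.ndarray | None
    stopped_epoch: int

    def predict(self, X) -> np.ndarray:
        Xm = np.atleast_2d(np.asarray(getattr(X, "scores", X), dtype=float))
        Z = (Xm - self.x_mean) / self.x_scale
        hidden, _ = _act(Z @ self.w1 + self.b1, self.config.activation)
        out = hidden @ self.w2 + self.b2
        return out * self.y_scale + self.y_mean


def ann_fit(
    scores,
    y,
    cfg: ANNConfig = ANNConfig(),
    monitor: tuple | None = None,
) -> ANNModel:
    """Backprop training on standardised scores, optional early stopping.

    ``monitor`` is an (X_mon, y_mon) pair disjoint from the training data;
    without one, training runs for ``max_epochs``.  Given a seed the loss
    trace is identical across runs.
    """
    X = np.atleast_2d(np.asarray(getattr(scores, "scores", scores), dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("scores and y disagree on sample count")
    x_mean, x_scale = X.mean(axis=0), X.std(axis=0, ddof=1)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    y_mean, y_scale = float(y.mean()), float(y.std(ddof=1))
    if y_scale == 0:
        raise ValueError("y is constant; nothing to learn")
    Z = (X - x_mean) / x_scale
    t = (y - y_mean) / y_scale
    rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden
    w1 = rng.normal(0.0, 1.0 / np.sqrt(X.shape[1]), size=(X.shape[1], h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
    b2 = 0.0
    if monitor is not None:
        Xm = np.atleast_2d(np.asarray(getattr(monitor[0], "scores", monitor[0]), dtype=float))
        ym = np.asarray(monitor[1], dtype=float).ravel()
        Zm = (Xm - x_mean) / x_scale
    lr = cfg.learning_rate
    n = Z.shape[0]
    train_trace, mon_trace = [], []
    best = (np.inf, None)
    rising = 0
    stopped = cfg.max_epochs
    for epoch in range(cfg.max_epochs):
        A, dA = _act(Z @ w1 + b1, cfg.activation)
        out = A @ w2 + b2
        err = out - t
        train_trace.append(float(np.sqrt(np.mean(err**2))) * y_scale)
        # full-batch gradients of ½·mean(err²)
        g_out = err / n
        gw2 = A.T @ g_out
        gb2 = g_out.sum()
        g_hidden = np.outer(g_out, w2) * dA
        gw1 = Z.T @ g_hidden
        gb1 = g_hidden.sum(axis=0)
        w1 -= lr * gw1
        b1 -= lr * gb1
        w2 -= lr * gw2
        b2 -= lr * gb2
        if monitor is not None:
            Am, _ = _act(Zm @ w1 + b1, cfg.activation)
            pred_m = (Am @ w2 + b2) * y_scale + y_mean
            rmse_m = float(np.sqrt(np.mean((pred_m - ym) ** 2)))
            mon_trace.append(rmse_m)
            if rmse_m < best[0]:
                best = (rmse_m, (w1.copy(), b1.copy(), w2.copy(), b2))
                rising = 0
            else:
                rising += 1
                if rising > cfg.patience:
                    stopped = epoch + 1
                    break
    if monitor is not None and best[1] is not None:
        w1, b1, w2, b2 = best[1]
    return ANNModel(
        cfg, w1, b1, w2, b2, x_mean, x_scale, y_mean, y_scale,
        np.asarray(train_trace),
        np.asarray(mon_trace) if monitor is not None else None,
        stopped,
    )


def hidden_size_sweep(scores, y, monitor, sizes, cfg: ANNConfig = ANNConfig()):
    """Trial-and-error architecture search: monitor RMSE per hidden size."""
    from dataclasses import replace

    rows = []
    for h in sizes:
        model = ann_fit(scores, y, replace(cfg, hidden=int(h)), monitor=monitor)
        rows.append({"hidden": int(h), "monitor_rmse": float(model.monitor_trace.min())})
    return rows


def load_presets() -> dict:
    """Model × analyte preset registry (preprocessing, compression, params)."""
    text = resources.files("mixcal.data").joinpath("presets.json").read_text()
    return json.loads(text)
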