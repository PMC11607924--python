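"""SIMPLS partial least squares (PLS1), cross-validation and compression.

Each analyte is calibrated separately (PLS1): the spectra matrix X and the
single concentration vector y are decomposed simultaneously into a small
number of latent variables (LVs) that capture the X–y covariance.  The
SIMPLS recursion works on successively deflated covariance vectors s = Xᵀy,
which for a single response is algebraically equivalent to NIPALS PLS1 but
needs no deflation of X itself.

The number of LVs is chosen from the leave-one-out PRESS curve by the
fewest-components rule: take the smallest model whose PRESS is statistically
indistinguishable (F ratio at a configurable quantile) from the global
minimum.  PCA and PLS score compression for downstream non-linear
regressors live here too, sharing the fitted projection bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import SpectraSet


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraSet):
        return X.absorbance
    return np.atleast_2d(np.asarray(X, dtype=float))


@dataclass
class PLSModel:
    """Fitted SIMPLS PLS1 model.

    ``coefs[:, h-1]`` is the regression vector using the first h LVs, on the
    centred scale; predictions add back the training means.  ``press`` is
    filled by :func:`loo_rmsecv` when cross-validation is run.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # wavelengths x LV (scores T = Xc @ weights)
    scores: np.ndarray     # samples x LV, orthonormal columns
    loadings: np.ndarray   # wavelengths x LV
    y_loadings: np.ndarray  # LV,
    coefs: np.ndarray      # wavelengths x LV
    max_lv: int
    n_lv: int | None = None
    press: np.ndarray | None = None
    rmsecv: np.ndarray | None = None

    def to_json(self) -> str:
        import json

        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefs": self.coefs.tolist(),
            "max_lv": self.max_lv,
            "n_lv": self.n_lv,
            "press": None if self.press is None else self.press.tolist(),
        }
        return json.dumps(payload, sort_keys=True)


def simpls_fit(X, y, max_lv: int) -> PLSModel:
    """Fit PLS1 by the SIMPLS recursion for 1..max_lv latent variables.

    X is centred internally (spectra should already be preprocessed; an
    extra centring is harmless and supplies the intercept).  Requires
    ``max_lv <= min(n_samples − 1, n_wavelengths)`` and non-constant y.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if y.size != n:
        raise ValueError(f"y has {y.size} entries for {n} samples")
    if max_lv < 1 or max_lv > min(n - 1, p):
        raise ValueError(
            f"max_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {max_lv}"
        )
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xm - x_mean
    yc = y - y_mean

    s = Xc.T @ yc
    R = np.zeros((p, max_lv))   # weights (scores = Xc @ R)
    T = np.zeros((n, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    V = np.zeros((p, max_lv))   # orthonormal loading basis for deflating s
    for a in range(max_lv):
        r = s.copy()
        t = Xc @ r
        norm_t = np.linalg.norm(t)
        if norm_t < 1e-300:
            raise ValueError(
                f"covariance exhausted at LV {a + 1}; lower max_lv (rank deficiency)"
            )
        t /= norm_t
        r /= norm_t
        p_a = Xc.T @ t
        q_a = float(yc @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a], T[:, a], P[:, a], q[a], V[:, a] = r, t, p_a, q_a, v
    coefs = np.cumsum(R * q, axis=1)
    return PLSModel(x_mean, y_mean, R, T, P, q, coefs, max_lv)


def pls_predict(model: PLSModel, X, n_lv: int | None = None) -> np.ndarray:
    """Predict concentrations with the first ``n_lv`` latent variables.

    ``n_lv = 0`` returns the training mean for every sample.
    """
    if n_lv is None:
        n_lv = model.n_lv if model.n_lv is not None else model.max_lv
    if n_lv < 0 or n_lv > model.max_lv:
        raise ValueError(f"n_lv must be in [0, {model.max_lv}], got {n_lv}")
    Xm = _as_matrix(X)
    if Xm.shape[1] != model.x_mean.size:
        raise ValueError(
            f"{Xm.shape[1]} wavelengths, model fitted with {model.x_mean.size}"
        )
    if n_lv == 0:
        return np.full(Xm.shape[0], model.y_mean)
    return (Xm - model.x_mean) @ model.coefs[:, n_lv - 1] + model.y_mean


def loo_rmsecv(X, y, max_lv: int) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out PRESS and RMSECV per latent-variable count.

    Refits SIMPLS on every n−1 subset and predicts the held-out sample at
    each truncation level; RMSECV(h) = sqrt(PRESS(h)/n).
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    press = np.zeros(max_lv)
    for i in range(n):
        keep = np.arange(n) != i
        sub = simpls_fit(Xm[keep], y[keep], max_lv)
        for h in range(1, max_lv + 1):
            pred = pls_predict(sub, Xm[i : i + 1], h)[0]
            press[h - 1] += (pred - y[i]) ** 2
    return press, np.sqrt(press / n)


def select_lv_haaland(press: np.ndarray, n: int, alpha: float = 0.25) -> tuple[int, np.ndarray]:
    """Fewest-components rule on a PRESS curve (Haaland–Thomas F test).

    Returns the smallest h whose PRESS ratio to the global minimum stays
    below the F(1−alpha; n, n) quantile, plus the ratio trace.
    """
    press = np.asarray(press, dtype=float)
    if press.size == 0:
        raise ValueError("empty PRESS curve")
    if not np.all(np.isfinite(press)):
        raise ValueError("PRESS curve contains non-finite values")
    h_star = int(np.argmin(press))
    denom = press[h_star] if press[h_star] > 0 else np.finfo(float).tiny
    ratios = press / denom
    f_crit = stats.f.ppf(1.0 - alpha, n, n)
    candidates = np.nonzero(ratios <= f_crit)[0]
    chosen = int(candidates[0]) + 1  # 1-based LV count
    return chosen, ratios


def fit_with_cv(X, y, max_lv: int = 10, alpha: float = 0.25) -> PLSModel:
    """SIMPLS fit + LOO cross-validation + fewest-components LV choice."""
    Xm = _as_matrix(X)
    max_lv = min(max_lv, Xm.shape[0] - 2, Xm.shape[1])
    model = simpls_fit(Xm, y, max_lv)
    press, rmsecv = loo_rmsecv(Xm, y, max_lv)
    model.press, model.rmsecv = press, rmsecv
    model.n_lv, _ = select_lv_haaland(press, Xm.shape[0], alpha)
    return model


@dataclass
class ScoreMatrix:
    """Compressed sample features with the basis to project new samples.

    ``method`` is "PCA" or "PLS"; ``scores`` is samples × k.  Projection is
    ``(X_new − mean) @ basis`` and reproduces the stored calibration scores.
    """

    scores: np.ndarray
    method: str
    mean: np.ndarray
    basis: np.ndarray  # wavelengths x k

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def project(self, X) -> np.ndarray:
        Xm = _as_matrix(X)
        if Xm.shape[1] != self.mean.size:
            raise ValueError("wavelength count does not match the fitted basis")
        return (Xm - self.mean) @ self.basis


def compress(X, y=None, k: int = 3, method: str = "PCA") -> ScoreMatrix:
    """Compress spectra to k PCA or PLS scores (PLS needs the response y)."""
    Xm = _as_matrix(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    mean = Xm.mean(axis=0)
    Xc = Xm - mean
    if method == "PCA":
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        if k > rank:
            raise ValueError(f"k={k} exceeds the matrix rank {rank}")
        basis = Vt[:k].T
        scores = U[:, :k] * s[:k]
        return ScoreMatrix(scores, "PCA", mean, basis)
    if method == "PLS":
        if y is None:
            raise ValueError("PLS compression requires y")
        rank = np.linalg.matrix_rank(Xc)
        if k > rank:
            raise ValueError(f"k={k} exceeds the matrix rank {rank}")
        model = simpls_fit(Xm, y, k)
        return ScoreMatrix(model.scores, "PLS", model.x_mean, model.weights)
    raise ValueError(f"unknown compression method {method!r}")
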