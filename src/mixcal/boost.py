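"""Regularised gradient-boosted regression trees (exact greedy, squared loss).

This is a native implementation of the boosting model used for the mixture
calibration: squared-error gradient boosting where each round fits a
regression tree to the current residuals by exhaustive (exact greedy) split
search.  With squared loss the per-sample hessian is 1, so the structure
score of a leaf with gradient sum G over H samples is −G²/(2(H+λ)) and a
split is kept only if its gain

    gain = ½ [ G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ) ] − γ

is positive.  Leaf weights are −G/(H+λ); predictions accumulate
``base_score + eta · Σ tree outputs``.  Split candidates are the midpoints
between consecutive sorted distinct feature values; ties break on the
lowest feature index then the lowest threshold, so fits are deterministic
across platforms.  Calibration sets here have ≤ 43 samples, so no histogram
approximation is needed or wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class GBTConfig:
    """Boosting hyperparameters.

    ``eta`` is the shrinkage applied to every tree's output; ``lam`` the L2
    penalty on leaf weights; ``gamma`` the per-split penalty;
    ``min_child_weight`` the minimum hessian sum per leaf, which for squared
    loss equals the minimum sample count.
    """

    eta: float = 0.3
    max_depth: int = 3
    num_round: int = 100
    lam: float = 1.0
    gamma: float = 0.0
    min_child_weight: float = 1.0
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.num_round < 1:
            raise ValueError("num_round must be >= 1")
        if self.lam < 0 or self.gamma < 0 or self.min_child_weight < 0:
            raise ValueError("lam, gamma and min_child_weight must be >= 0")


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


@dataclass
class GBTModel:
    """An ordered forest of regression trees plus the boosting metadata.

    ``loss_trace[r]`` is the training MSE after round r+1; it is
    non-increasing for any eta ≤ 1 (asserted at fit time).
    """

    base_score: float
    trees: list[list[_Node]]
    config: GBTConfig
    loss_trace: np.ndarray

    def to_json(self) -> str:
        payload = {
            "base_score": self.base_score,
            "config": asdict(self.config),
            "loss_trace": self.loss_trace.tolist(),
            "trees": [[asdict(n) for n in tree] for tree in self.trees],
        }
        return json.dumps(payload, sort_keys=True)


def best_split(x: np.ndarray, g: np.ndarray, h: np.ndarray,
               lam: float, gamma: float, min_child_weight: float):
    """Exact greedy search over one feature: (gain, threshold) or None.

    Thresholds are midpoints between consecutive distinct sorted values;
    samples with value strictly below the threshold go left.
    """
    order = np.argsort(x, kind="stable")
    xs, gs, hs = x[order], g[order], h[order]
    if xs[0] == xs[-1]:
        return None
    G, H = gs.sum(), hs.sum()
    parent = G * G / (H + lam)
    gl = np.cumsum(gs)[:-1]
    hl = np.cumsum(hs)[:-1]
    gr, hr = G - gl, H - hl
    valid = (xs[1:] != xs[:-1]) & (hl >= min_child_weight) & (hr >= min_child_weight)
    if not valid.any():
        return None
    gain = 0.5 * (gl * gl / (hl + lam) + gr * gr / (hr + lam) - parent) - gamma
    gain[~valid] = -np.inf
    i = int(np.argmax(gain))  # first maximum -> lowest threshold on ties
    return float(gain[i]), float(0.5 * (xs[i] + xs[i + 1]))


def _build_tree(X: np.ndarray, g: np.ndarray, h: np.ndarray, cfg: GBTConfig) -> list[_Node]:
    nodes: list[_Node] = []

    def grow(idx: np.ndarray, depth: int) -> int:
        node_id = len(nodes)
        nodes.append(_Node())
        G, H = g[idx].sum(), h[idx].sum()
        choice = None
        if depth < cfg.max_depth and idx.size >= 2:
            for f in range(X.shape[1]):  # lowest feature index wins ties
                found = best_split(X[idx, f], g[idx], h[idx],
                                   cfg.lam, cfg.gamma, cfg.min_child_weight)
                if found is not None and found[0] > 0 and (
                    choice is None or found[0] > choice[0] + 1e-15
                ):
                    choice = (found[0], f, found[1])
        if choice is None:
            nodes[node_id].value = -G / (H + cfg.lam)
            return node_id
        _, f, thr = choice
        mask = X[idx, f] < thr
        nodes[node_id].feature = f
        nodes[node_id].threshold = thr
        nodes[node_id].left = grow(idx[mask], depth + 1)
        nodes[node_id].right = grow(idx[~mask], depth + 1)
        return node_id

    grow(np.arange(X.shape[0]), 0)
    return nodes


def _tree_predict(nodes: list[_Node], X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        node = nodes[0]
        while not node.is_leaf:
            node = nodes[node.left] if row[node.feature] < node.threshold else nodes[node.right]
        out[i] = node.value
    return out


def gbt_fit(features, y, cfg: GBTConfig = GBTConfig()) -> GBTModel:
    """Boost ``num_round`` trees against squared-error residuals.

    ``features`` may be an array or a :class:`mixcal.latent.ScoreMatrix`.
    ``base_score`` is the training mean of y.
    """
    X = np.atleast_2d(np.asarray(getattr(features, "scores", features), dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.size == 0 or y.size == 0:
        raise ValueError("empty training data")
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} feature rows for {y.size} targets")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and y must be finite")
    base = float(y.mean())
    pred = np.full(y.size, base)
    ones = np.ones(y.size)
    trees: list[list[_Node]] = []
    trace = np.empty(cfg.num_round)
    for r in range(cfg.num_round):
        g = pred - y  # gradient of ½(pred−y)²; hessian = 1
        tree = _build_tree(X, g, ones, cfg)
        pred = pred + cfg.eta * _tree_predict(tree, X)
        trees.append(tree)
        trace[r] = float(np.mean((pred - y) ** 2))
    if np.any(np.diff(trace) > 1e-10):
        raise AssertionError("training loss increased during boosting")
    return GBTModel(base, trees, cfg, trace)


def gbt_predict(model: GBTModel, features) -> np.ndarray:
    """base_score + eta · Σ tree outputs, strictly-less-than goes left."""
    X = np.atleast_2d(np.asarray(getattr(features, "scores", features), dtype=float))
    if model.trees:
        n_feat = 1 + max(
            (n.feature for tree in model.trees for n in tree if not n.is_leaf),
            default=0,
        )
        if X.shape[1] < n_feat:
            raise ValueError(f"model uses feature index {n_feat - 1}, "
                             f"got {X.shape[1]} features")
    out = np.full(X.shape[0], model.base_score)
    for tree in model.trees:
        out += model.config.eta * _tree_predict(tree, X)
    return out


def gbt_cv_select(
    features,
    y,
    grid: dict[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
    base: GBTConfig = GBTConfig(),
) -> tuple[GBTConfig, list[dict]]:
    """K-fold CV over an (eta, max_depth, num_round) grid.

    Fold assignment is a seeded permutation split into contiguous blocks.
    The winner has the lowest mean validation RMSE; ties break toward the
    smaller num_round, then max_depth, then eta.  Returns the chosen config
    and the full CV table (one dict per grid point).
    """
    X = np.atleast_2d(np.asarray(getattr(features, "scores", features), dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"{folds} folds for {n} samples")
    if grid is None:
        grid = {"eta": [0.1, 0.3, 0.5], "max_depth": [1, 3, 6],
                "num_round": [50, 150, 300]}
    keys = sorted(grid)
    points = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
    if not points:
        raise ValueError("empty grid")
    perm = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f
    table = []
    for point in points:
        cfg = GBTConfig(**{**asdict(base), **point, "seed": seed})
        errs = []
        for f in range(folds):
            val = fold_of == f
            model = gbt_fit(X[~val], y[~val], cfg)
            pred = gbt_predict(model, X[val])
            errs.append(float(np.sqrt(np.mean((pred - y[val]) ** 2))))
        table.append({**point, "mean_rmse": float(np.mean(errs))})
    def sort_key(row):
        return (row["mean_rmse"],
                row.get("num_round", 0), row.get("max_depth", 0), row.get("eta", 0))
    best_row = min(table, key=sort_key)
    best = GBTConfig(**{**asdict(base),
                        **{k: best_row[k] for k in keys}, "seed": seed})
    return best, table
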