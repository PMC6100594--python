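"""NIPALS PLS1 regression with cross-validated latent-component selection.

This is the computational kernel of the interval search and the
preprocessing comparison. X and y are mean-centred (no variance scaling; SNV
already normalises spectra). Components are extracted by the NIPALS
deflation sequence for a single response; the component count is chosen by
the minimum root-mean-square error of cross-validation (RMSECV), leave-one-out
by default, with ties broken toward the smaller count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "CVScheme",
    "fit_pls",
    "predict",
    "rmsecv",
    "select_n_components",
    "DegenerateTargetError",
]


class DegenerateTargetError(ValueError):
    """y has zero variance; PLS1 weights are undefined."""


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout: leave-one-out or contiguous k-fold."""

    kind: str = "loo"  # "loo" | "kfold"
    k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("loo", "kfold"):
            raise ValueError("kind must be 'loo' or 'kfold'")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")

    def folds(self, n: int) -> list[np.ndarray]:
        """Held-out index arrays, contiguous and covering 0..n-1."""
        if self.kind == "loo":
            return [np.array([i]) for i in range(n)]
        if self.k > n:
            raise ValueError(f"k={self.k} folds but only n={n} samples")
        return [chunk for chunk in np.array_split(np.arange(n), self.k)]


@dataclass
class PLSModel:
    """Fitted PLS1 model on mean-centred data.

    ``coef`` is the regression vector b such that
    yhat = (X - x_mean) @ b + y_mean.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A) NIPALS weight vectors
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A) training scores
    coef: np.ndarray  # (p,)
    fitted: np.ndarray = field(default=None)  # training predictions

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coef": self.coef.tolist(),
            "y_loadings": self.y_loadings.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS with X-deflation.

    Per component: w = X'y normalised, t = Xw, p = X't/t't, q = y't/t't,
    then X <- X - t p' and y <- y - q t. The regression vector on centred
    data is b = W (P'W)^{-1} q.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components={n_components} outside [1, {max_comp}]")
    if np.ptp(y) == 0:
        raise DegenerateTargetError("y is constant")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # X carries no further covariance with y; truncate
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_components = a
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-28:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_components = a
            break
        pa = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
    if n_components == 0:
        raise DegenerateTargetError("no usable PLS component (X'y vanishes)")

    coef = W @ np.linalg.solve(P.T @ W, q)
    fitted = Xc @ coef + y_mean
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        fitted=fitted,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """yhat = (X - x_mean) @ b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(f"X has {X.shape[1]} channels, model expects {model.x_mean.size}")
    return (X - model.x_mean) @ model.coef + model.y_mean


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scheme: CVScheme | None = None,
) -> float:
    """Root-mean-square error over held-out samples, refitting per fold.

    The component count is capped per fold at the fold's own rank bound, so a
    request feasible on the full set never fails on a slightly smaller fold.
    """
    scheme = scheme or CVScheme()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    sq_sum = 0.0
    for held in scheme.folds(n):
        train = np.setdiff1d(np.arange(n), held, assume_unique=True)
        y_tr = y[train]
        if np.ptp(y_tr) == 0:
            raise DegenerateTargetError("training fold has constant y")
        a = min(n_components, train.size - 1, X.shape[1])
        model = fit_pls(X[train], y_tr, a)
        resid = predict(model, X[held]) - y[held]
        sq_sum += float(resid @ resid)
    return float(np.sqrt(sq_sum / n))


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    max_pc: int = 10,
    scheme: CVScheme | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the component count minimising RMSECV over 1..max_pc.

    Returns the winner and the full RMSECV curve. Ties resolve to the
    smallest count (parsimony). ``max_pc`` is clipped to the rank bound.
    """
    if max_pc < 1:
        raise ValueError("max_pc must be >= 1")
    X = np.asarray(X, dtype=float)
    n = np.asarray(y).size
    hi = min(max_pc, n - 1, X.shape[1])
    curve = np.array([rmsecv(X, y, a, scheme) for a in range(1, hi + 1)])
    best = int(np.argmin(curve)) + 1  # argmin returns first minimum -> smallest count
    return best, curve
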