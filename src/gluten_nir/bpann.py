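"""PCA-compressed backpropagation neural network calibration.

The selected wavelength channels are compressed by mean-centred PCA; the
leading scores feed a three-layer feed-forward network (sigmoid hidden
layer, single linear output neuron — the predicted analyte value) trained by
full-batch gradient descent with momentum on squared error. The input PC
count is chosen by the minimum cross-validated RMSECV, the same criterion as
for the PLS component count. The nonlinear hidden layer is what lets this
model outperform linear PLS when the analyte-spectrum response saturates,
as it does for disulfide content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from gluten_nir.pls import CVScheme

__all__ = [
    "PCABasis",
    "ANNConfig",
    "ANNModel",
    "pca_fit",
    "pca_transform",
    "train_bpann",
    "predict_ann",
    "select_pc_count",
    "fit_ann",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class PCABasis:
    """Mean-centred PCA basis over the selected channels."""

    loadings: np.ndarray  # (n_channels_selected, n_pc), orthonormal columns
    explained_variance_ratio: np.ndarray  # (n_pc,)
    x_mean: np.ndarray  # (n_channels_selected,)
    n_pc: int


def pca_fit(X_selected: np.ndarray, n_pc: int) -> PCABasis:
    """Fit mean-centred PCA; scores are centred X projected on the loadings."""
    X = np.asarray(X_selected, dtype=float)
    bound = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_pc <= bound:
        raise ValueError(f"n_pc={n_pc} outside [1, {bound}]")
    p = PCA(n_components=n_pc, svd_solver="full")
    p.fit(X)
    return PCABasis(
        loadings=p.components_.T.copy(),
        explained_variance_ratio=p.explained_variance_ratio_.copy(),
        x_mean=p.mean_.copy(),
        n_pc=n_pc,
    )


def pca_transform(basis: PCABasis, X_selected: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X_selected, dtype=float))
    if X.shape[1] != basis.x_mean.size:
        raise ValueError(f"X has {X.shape[1]} channels, basis expects {basis.x_mean.size}")
    return (X - basis.x_mean) @ basis.loadings


@dataclass(frozen=True)
class ANNConfig:
    """Training hyperparameters of the backprop network.

    Defaults: 5 sigmoid hidden units, learning rate 0.05, momentum 0.9,
    up to 2000 full-batch epochs, early stop when the loss change falls
    below 1e-8. Weights initialise uniformly in [-0.5, 0.5] from the run
    seed. The target is affinely scaled into [0.1, 0.9] during training so
    the squared-error surface is comparable across analytes.
    """

    hidden_size: int = 5
    learning_rate: float = 0.05
    momentum: float = 0.9
    epochs: int = 2000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class ANNModel:
    """Fitted three-layer network plus its input compression and scalings."""

    pca: PCABasis | None
    hidden_size: int
    w_in: np.ndarray  # (n_pc, hidden)
    b_in: np.ndarray  # (hidden,)
    w_out: np.ndarray  # (hidden,)
    b_out: float
    score_mean: np.ndarray  # input standardisation over training scores
    score_scale: np.ndarray
    y_min: float  # y scaled to [0.1, 0.9] internally
    y_max: float
    config: ANNConfig = field(default_factory=ANNConfig)
    seed: int = 0
    final_loss: float = float("nan")
    epochs_run: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hidden_size": self.hidden_size,
            "w_in": self.w_in.tolist(),
            "b_in": self.b_in.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
            "score_mean": self.score_mean.tolist(),
            "score_scale": self.score_scale.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "seed": self.seed,
            "config": {
                "hidden_size": self.config.hidden_size,
                "learning_rate": self.config.learning_rate,
                "momentum": self.config.momentum,
                "epochs": self.config.epochs,
                "tol": self.config.tol,
            },
            "pca": None
            if self.pca is None
            else {
                "loadings": self.pca.loadings.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
                "x_mean": self.pca.x_mean.tolist(),
                "n_pc": self.pca.n_pc,
            },
        }
        Path(path).write_text(json.dumps(payload))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def train_bpann(
    scores: np.ndarray,
    y: np.ndarray,
    config: ANNConfig | None = None,
    seed: int = 0,
    pca: PCABasis | None = None,
) -> ANNModel:
    """Train the network on PCA scores by backpropagation with momentum.

    Inputs are standardised per component (PCA scores span orders of
    magnitude across components and would otherwise saturate the sigmoid);
    y is scaled into [0.1, 0.9]. Identical seeds give bitwise-identical
    weights. Raises :class:`DivergenceError` if the loss becomes NaN.
    """
    config = config or ANNConfig()
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(S)):
        raise ValueError("scores must be finite")
    n, d = S.shape
    if y.size != n:
        raise ValueError("scores and y length mismatch")

    s_mean = S.mean(axis=0)
    s_scale = S.std(axis=0, ddof=0)
    s_scale[s_scale == 0] = 1.0
    Ss = (S - s_mean) / s_scale
    y_min, y_max = float(y.min()), float(y.max())
    span = y_max - y_min if y_max > y_min else 1.0
    ys = 0.1 + 0.8 * (y - y_min) / span

    rng = np.random.default_rng(seed)
    h = config.hidden_size
    w_in = rng.uniform(-0.5, 0.5, size=(d, h))
    b_in = rng.uniform(-0.5, 0.5, size=h)
    w_out = rng.uniform(-0.5, 0.5, size=h)
    b_out = float(rng.uniform(-0.5, 0.5))

    v_w_in = np.zeros_like(w_in)
    v_b_in = np.zeros_like(b_in)
    v_w_out = np.zeros_like(w_out)
    v_b_out = 0.0
    lr, mom = config.learning_rate, config.momentum
    prev_loss = np.inf
    final_loss = np.nan
    epoch = 0
    for epoch in range(1, config.epochs + 1):
        hidden = _sigmoid(Ss @ w_in + b_in)
        yhat = hidden @ w_out + b_out
        err = yhat - ys
        loss = float(err @ err) / n
        if not np.isfinite(loss):
            raise DivergenceError(
                f"loss became non-finite at epoch {epoch} (learning_rate={lr})"
            )
        d_out = 2.0 * err / n
        g_w_out = hidden.T @ d_out
        g_b_out = float(d_out.sum())
        d_hidden = np.outer(d_out, w_out) * hidden * (1.0 - hidden)
        g_w_in = Ss.T @ d_hidden
        g_b_in = d_hidden.sum(axis=0)

        v_w_in = mom * v_w_in - lr * g_w_in
        v_b_in = mom * v_b_in - lr * g_b_in
        v_w_out = mom * v_w_out - lr * g_w_out
        v_b_out = mom * v_b_out - lr * g_b_out
        w_in += v_w_in
        b_in += v_b_in
        w_out += v_w_out
        b_out += v_b_out

        final_loss = loss
        if abs(prev_loss - loss) < config.tol:
            break
        prev_loss = loss

    return ANNModel(
        pca=pca,
        hidden_size=h,
        w_in=w_in,
        b_in=b_in,
        w_out=w_out,
        b_out=b_out,
        score_mean=s_mean,
        score_scale=s_scale,
        y_min=y_min,
        y_max=y_max,
        config=config,
        seed=seed,
        final_loss=final_loss,
        epochs_run=epoch,
    )


def predict_ann(model: ANNModel, X_selected: np.ndarray) -> np.ndarray:
    """Project onto the PCA basis (if stored), forward pass, unscale to umol/g."""
    X = np.atleast_2d(np.asarray(X_selected, dtype=float))
    scores = pca_transform(model.pca, X) if model.pca is not None else X
    if scores.shape[1] != model.w_in.shape[0]:
        raise ValueError(
            f"input width {scores.shape[1]} does not match network input {model.w_in.shape[0]}"
        )
    Ss = (scores - model.score_mean) / model.score_scale
    hidden = _sigmoid(Ss @ model.w_in + model.b_in)
    ys = hidden @ model.w_out + model.b_out
    span = model.y_max - model.y_min if model.y_max > model.y_min else 1.0
    return model.y_min + (ys - 0.1) * span / 0.8


def fit_ann(
    X_selected: np.ndarray,
    y: np.ndarray,
    n_pc: int,
    config: ANNConfig | None = None,
    seed: int = 0,
) -> ANNModel:
    """Convenience: PCA-compress the selected channels, then train the network."""
    basis = pca_fit(X_selected, n_pc)
    scores = pca_transform(basis, X_selected)
    return train_bpann(scores, y, config=config, seed=seed, pca=basis)


def select_pc_count(
    X_selected: np.ndarray,
    y: np.ndarray,
    max_pc: int = 10,
    config: ANNConfig | None = None,
    scheme: CVScheme | None = None,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the PCA input width by cross-validated network RMSECV.

    For each candidate count, the PCA basis and the network are refit on
    every training fold (no leakage from held-out spectra). Returns the
    argmin and the full curve; ties resolve to the smaller count.
    """
    if max_pc < 1:
        raise ValueError("max_pc must be >= 1")
    config = config or ANNConfig()
    scheme = scheme or CVScheme(kind="kfold", k=5)
    X = np.asarray(X_selected, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds = scheme.folds(n)
    hi = min(max_pc, min(len(np.setdiff1d(np.arange(n), f)) for f in folds) - 1, X.shape[1])
    curve = np.empty(hi)
    for n_pc in range(1, hi + 1):
        sq = 0.0
        for fi, held in enumerate(folds):
            train = np.setdiff1d(np.arange(n), held, assume_unique=True)
            model = fit_ann(X[train], y[train], n_pc, config=config, seed=seed + fi)
            resid = predict_ann(model, X[held]) - y[held]
            sq += float(resid @ resid)
        curve[n_pc - 1] = np.sqrt(sq / n)
    best = int(np.argmin(curve)) + 1
    return best, curve
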