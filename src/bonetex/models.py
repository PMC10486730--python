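"""BMD/BMC estimation models: normal-equation linear regression and a
small fully-connected ReLU network.

The linear model estimates a DXA target as a weighted combination of the
45 texture features plus a bias, ŷ = w₀ + Σ wᵢ xᵢ, with weights chosen to
minimize the sum of squared errors via the Moore–Penrose pseudoinverse
(the minimum-norm least-squares solution, computed by a rank-revealing
SVD rather than an explicit normal-matrix inverse).  The whole cohort is
used for fitting — no train/test split, no regularization — because the
sample count comfortably exceeds the 46 trainable weights.

The neural alternative is a fixed 8-8-2 ReLU architecture with a single
linear output, trained by seeded full-batch gradient descent on the mean
squared error.  Features and target are z-scored before either fit and
predictions are mapped back to original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .core import (
    FEATURE_ORDER_VERSION,
    ContractError,
    InvalidParameterError,
    TrainingDivergedError,
    UndefinedCorrelationError,
    UnderdeterminedFitError,
)
from .features import FEATURE_NAMES

__all__ = [
    "DesignMatrix",
    "LinearModel",
    "ANNSpec",
    "ANNModel",
    "FitResult",
    "normalize",
    "fit_lr",
    "predict",
    "fit_ann",
    "evaluate",
]

N_FEATURES = 45
N_COLUMNS = N_FEATURES + 1  # bias + features


@dataclass
class DesignMatrix:
    """Normalized design: bias column of ones + 45 z-scored feature columns.

    Normalization parameters (per-column center/scale, and the target's)
    are retained so that fitted weights can be applied to new subjects and
    predictions mapped back to original units.  Zero-variance columns are
    centered only (scale left at 1) and flagged.
    """

    X: np.ndarray
    y: np.ndarray            # normalized target
    y_raw: np.ndarray        # target in original units
    feature_names: tuple[str, ...]
    centers: np.ndarray
    scales: np.ndarray
    zero_variance: np.ndarray
    target_center: float
    target_scale: float
    method: str = "zscore"

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class LinearModel:
    """Fitted linear estimator: 46 weights (bias first) plus the
    normalization needed to apply them."""

    weights: np.ndarray
    target_name: str
    feature_names: tuple[str, ...]
    centers: np.ndarray
    scales: np.ndarray
    zero_variance: np.ndarray
    target_center: float
    target_scale: float
    rank: int
    method: str = "zscore"
    feature_order_version: str = FEATURE_ORDER_VERSION

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_COLUMNS,):
            raise InvalidParameterError("LinearModel needs exactly 46 weights")
        if not np.all(np.isfinite(self.weights)):
            raise InvalidParameterError("non-finite weights")

    @property
    def rank_deficient(self) -> bool:
        return self.rank < N_COLUMNS

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_order_version": self.feature_order_version,
            "target_name": self.target_name,
            "weights": self.weights.tolist(),
            "feature_names": list(self.feature_names),
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "zero_variance": self.zero_variance.astype(bool).tolist(),
            "target_center": self.target_center,
            "target_scale": self.target_scale,
            "rank": int(self.rank),
            "normalization": self.method,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        payload = json.loads(Path(path).read_text())
        if payload["feature_order_version"] != FEATURE_ORDER_VERSION:
            raise ContractError(
                "model was fitted under a different feature order version"
            )
        return cls(
            weights=np.array(payload["weights"]),
            target_name=payload["target_name"],
            feature_names=tuple(payload["feature_names"]),
            centers=np.array(payload["centers"]),
            scales=np.array(payload["scales"]),
            zero_variance=np.array(payload["zero_variance"], dtype=bool),
            target_center=payload["target_center"],
            target_scale=payload["target_scale"],
            rank=payload["rank"],
            method=payload.get("normalization", "zscore"),
        )


@dataclass
class FitResult:
    """Goodness-of-fit summary of one model on its fitting cohort."""

    predictions: np.ndarray  # original units
    pearson_r: float
    sse: float               # Σ (y − ŷ)², original units
    mse: float               # sse / n
    df_resid: int
    weight_se: np.ndarray | None = None  # normalized scale; None for ANN
    rank_deficient: bool = False
    model_kind: str = "lr"
    target_name: str = ""


def normalize(
    features: np.ndarray,
    target: np.ndarray,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    method: str = "zscore",
) -> DesignMatrix:
    """Build the 46-column design matrix with per-column normalization.

    ``method`` is ``"zscore"`` (zero mean, unit variance; default) or
    ``"minmax"`` (map to [0, 1]).  Requires strictly more subjects than
    design columns so the full-rank normal-equation fit is determined.
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if F.ndim != 2 or F.shape[1] != N_FEATURES:
        raise InvalidParameterError(f"features must be (n, {N_FEATURES})")
    if F.shape[0] != y.size:
        raise InvalidParameterError("feature and target row counts differ")
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("non-finite entries in features or target")
    n = F.shape[0]
    if n < N_COLUMNS + 1:
        raise UnderdeterminedFitError(
            f"need at least {N_COLUMNS + 1} subjects for a determined "
            f"{N_COLUMNS}-column fit; got {n}"
        )
    if method not in ("zscore", "minmax"):
        raise InvalidParameterError("method must be 'zscore' or 'minmax'")

    if method == "zscore":
        centers = F.mean(axis=0)
        scales = F.std(axis=0)
        t_center, t_scale = float(y.mean()), float(y.std())
    else:
        centers = F.min(axis=0)
        scales = F.max(axis=0) - F.min(axis=0)
        t_center, t_scale = float(y.min()), float(y.max() - y.min())

    # a column is degenerate when its spread is zero up to float round-off
    zero_var = scales <= 1e-12 * np.maximum(1.0, np.abs(centers))
    scales = np.where(zero_var, 1.0, scales)
    if t_scale <= 0:
        raise InvalidParameterError("constant target cannot be normalized")

    Xf = (F - centers) / scales
    X = np.column_stack([np.ones(n), Xf])
    return DesignMatrix(
        X=X,
        y=(y - t_center) / t_scale,
        y_raw=y,
        feature_names=tuple(feature_names),
        centers=centers,
        scales=scales,
        zero_variance=zero_var,
        target_center=t_center,
        target_scale=t_scale,
        method=method,
    )


def denormalize_target(design_or_model, y_norm: np.ndarray) -> np.ndarray:
    """Map a normalized target back to original units."""
    return (
        np.asarray(y_norm, dtype=float) * design_or_model.target_scale
        + design_or_model.target_center
    )


def _ols_standard_errors(X: np.ndarray, resid: np.ndarray, rank: int) -> np.ndarray | None:
    """Classical OLS weight standard errors; None when no df or rank-deficient."""
    n, p = X.shape
    df = n - p
    if df < 1 or rank < p:
        return None
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return np.sqrt(s2 * np.diag(xtx_inv))


def fit_lr(design: DesignMatrix, target_name: str = "") -> tuple[LinearModel, FitResult]:
    """Minimum-norm least-squares fit of the 46 weights by pseudoinverse.

    A rank-deficient design does not fail: the pseudoinverse returns the
    minimum-norm solution and the model is flagged ``rank_deficient``.
    """
    X, y = design.X, design.y
    w = np.linalg.pinv(X) @ y
    rank = int(np.linalg.matrix_rank(X))

    yhat_norm = X @ w
    predictions = denormalize_target(design, yhat_norm)
    resid_norm = y - yhat_norm
    se = _ols_standard_errors(X, resid_norm, rank)

    model = LinearModel(
        weights=w,
        target_name=target_name,
        feature_names=design.feature_names,
        centers=design.centers,
        scales=design.scales,
        zero_variance=design.zero_variance,
        target_center=design.target_center,
        target_scale=design.target_scale,
        rank=rank,
        method=design.method,
    )
    r, sse, mse = evaluate(predictions, design.y_raw)
    fit = FitResult(
        predictions=predictions,
        pearson_r=r,
        sse=sse,
        mse=mse,
        df_resid=design.n - N_COLUMNS,
        weight_se=se,
        rank_deficient=model.rank_deficient,
        model_kind="lr",
        target_name=target_name,
    )
    return model, fit


def predict(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Apply a fitted linear model to raw (unnormalized) feature rows."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != N_FEATURES:
        raise ContractError(f"expected {N_FEATURES} features, got {F.shape[1]}")
    Xf = (F - model.centers) / model.scales
    yn = model.weights[0] + Xf @ model.weights[1:]
    return denormalize_target(model, yn)


@dataclass(frozen=True)
class ANNSpec:
    """Fixed 8-8-2 ReLU architecture and its training hyperparameters.

    Training is full-batch Adam on the mean squared error, restarted
    from ``n_restarts`` seeded He initializations with the lowest final
    training loss kept — tiny ReLU networks routinely land in dead-unit
    plateaus from a single start, and the restart ensemble is the
    smallest deterministic remedy.
    """

    hidden: tuple[int, int, int] = (8, 8, 2)
    learning_rate: float = 1e-2
    epochs: int = 5000
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.hidden) != (8, 8, 2):
            raise InvalidParameterError("hidden layer widths are fixed at (8, 8, 2)")
        if self.learning_rate <= 0 or self.epochs < 0:
            raise InvalidParameterError("learning_rate > 0 and epochs >= 0 required")
        if self.n_restarts < 1:
            raise InvalidParameterError("n_restarts must be >= 1")


@dataclass
class ANNModel:
    """Trained network weights plus the normalization to apply them."""

    layers: list  # [(W, b), ...] with ReLU on all but the last
    spec: ANNSpec
    feature_names: tuple[str, ...] = FEATURE_NAMES
    centers: np.ndarray = field(default_factory=lambda: np.zeros(N_FEATURES))
    scales: np.ndarray = field(default_factory=lambda: np.ones(N_FEATURES))
    target_center: float = 0.0
    target_scale: float = 1.0

    def forward(self, Xf: np.ndarray) -> np.ndarray:
        a = Xf
        for W, b in self.layers[:-1]:
            a = np.maximum(a @ W + b, 0.0)
        W, b = self.layers[-1]
        return (a @ W + b).ravel()

    def predict(self, features: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(features, dtype=float))
        if F.shape[1] != N_FEATURES:
            raise ContractError(f"expected {N_FEATURES} features")
        Xf = (F - self.centers) / self.scales
        return self.forward(Xf) * self.target_scale + self.target_center


def _train_once(Xf, y, spec: ANNSpec, init_seed: int):
    """One Adam run from a He initialization; returns (layers, final loss)."""
    n = Xf.shape[0]
    rng = np.random.default_rng(init_seed)
    dims = [N_FEATURES, *spec.hidden, 1]
    layers = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        layers.append([W, np.zeros(fan_out)])
    m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
    v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    lr = spec.learning_rate
    loss = float("inf")
    for epoch in range(spec.epochs):
        # forward with cached activations; overflow is caught via the loss
        with np.errstate(over="ignore", invalid="ignore"):
            acts = [Xf]
            a = Xf
            for W, b in layers[:-1]:
                a = np.maximum(a @ W + b, 0.0)
                acts.append(a)
            W, b = layers[-1]
            out = (a @ W + b).ravel()

            err = out - y
            loss = float(err @ err) / n
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"loss diverged at epoch {epoch} (learning_rate={lr})"
            )

        # backward: d(mean squared error)/d out
        delta = (2.0 / n) * err[:, None]
        grads = [None] * len(layers)
        for li in range(len(layers) - 1, -1, -1):
            W, b = layers[li]
            grads[li] = (acts[li].T @ delta, delta.sum(axis=0))
            if li > 0:
                delta = (delta @ W.T) * (acts[li] > 0)
        t = epoch + 1
        for li, grad_pair in enumerate(grads):
            for k, g in enumerate(grad_pair):
                m[li][k] = beta1 * m[li][k] + (1 - beta1) * g
                v[li][k] = beta2 * v[li][k] + (1 - beta2) * g * g
                m_hat = m[li][k] / (1 - beta1**t)
                v_hat = v[li][k] / (1 - beta2**t)
                layers[li][k] = layers[li][k] - lr * m_hat / (np.sqrt(v_hat) + eps)

    if spec.epochs == 0:
        a = Xf
        for W, b in layers[:-1]:
            a = np.maximum(a @ W + b, 0.0)
        out = (a @ layers[-1][0] + layers[-1][1]).ravel()
        loss = float((out - y) @ (out - y)) / n
    return layers, loss


def fit_ann(design: DesignMatrix, spec: ANNSpec | None = None, target_name: str = "") -> tuple[ANNModel, FitResult]:
    """Train the 8-8-2 ReLU network; deterministic given ``spec.seed``.

    Runs ``spec.n_restarts`` full-batch Adam fits from independent seeded
    initializations and keeps the one with the lowest final training
    loss.  Raises :class:`TrainingDivergedError` if the loss goes
    non-finite.
    """
    spec = spec if spec is not None else ANNSpec()
    Xf = design.X[:, 1:]  # the network learns its own bias terms
    y = design.y
    n = Xf.shape[0]

    seed_rng = np.random.default_rng(spec.seed)
    init_seeds = seed_rng.integers(0, 2**31 - 1, size=spec.n_restarts)
    layers, best_loss = None, float("inf")
    for init_seed in init_seeds:
        cand, loss = _train_once(Xf, y, spec, int(init_seed))
        if loss < best_loss:
            layers, best_loss = cand, loss

    model = ANNModel(
        layers=[(W.copy(), b.copy()) for W, b in layers],
        spec=spec,
        feature_names=design.feature_names,
        centers=design.centers,
        scales=design.scales,
        target_center=design.target_center,
        target_scale=design.target_scale,
    )
    predictions = denormalize_target(design, model.forward(Xf))
    try:
        r, sse, mse = evaluate(predictions, design.y_raw)
    except UndefinedCorrelationError:
        # a dead-ReLU collapse can produce constant output; report r = nan
        resid = design.y_raw - predictions
        r, sse, mse = float("nan"), float(resid @ resid), float(resid @ resid) / n
    fit = FitResult(
        predictions=predictions,
        pearson_r=r,
        sse=sse,
        mse=mse,
        df_resid=n - N_COLUMNS,
        weight_se=None,
        model_kind="ann",
        target_name=target_name,
    )
    return model, fit


def evaluate(predictions: np.ndarray, references: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation plus both squared-error conventions.

    Returns ``(pearson_r, sse, mse)`` where ``sse = Σ (y − ŷ)²`` and
    ``mse = sse / n``; both are reported because either convention may be
    meant by a printed "MSE".
    """
    yhat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(references, dtype=float).ravel()
    if yhat.size != y.size:
        raise ContractError("prediction and reference lengths differ")
    if y.size < 3:
        raise ContractError("need at least 3 points to evaluate")
    if yhat.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance in predictions or references"
        )
    r = float(sps.pearsonr(yhat, y).statistic)
    resid = y - yhat
    sse = float(resid @ resid)
    return r, sse, sse / y.size
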