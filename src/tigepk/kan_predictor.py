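"""Kolmogorov-Arnold network (KAN) with learnable B-spline edge functions.

By the Kolmogorov-Arnold representation theorem any continuous
multivariate function can be written as a composition of sums of
univariate functions. A KAN layer realizes this literally: every edge
(i -> j) carries its own learnable univariate function

    phi_ji(x) = w_ji * silu(x) + sum_m c_jim * B_m(x)

(a fixed smooth base activation plus a cubic B-spline on a uniform grid),
and node j outputs the plain sum over incoming edges. The default
architecture here is [d_in, 8, 1]: one hidden layer of width 8, a cubic
spline with 5 grid intervals on [-1, 1] per edge, inputs min-max
normalized to [-1, 1] on the training data only. Outside the grid the
spline is continued linearly from the edge (value + edge slope), so
far-out inputs degrade gracefully instead of vanishing.

Training is full-batch Adam on MSE (regression, on a standardized target)
or binary cross-entropy through a logistic link (classification), with
best-validation-epoch snapshotting. Everything is plain numpy and fully
deterministic given the seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineEdge",
    "KANNetwork",
    "TrainConfig",
    "EvalReport",
    "TrainingDivergedError",
    "uniform_knots",
    "bspline_basis",
    "bspline_basis_and_deriv",
    "train",
    "evaluate",
    "auc_rank",
]


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# B-spline machinery
# ---------------------------------------------------------------------------

def uniform_knots(lo: float = -1.0, hi: float = 1.0, n_intervals: int = 5, order: int = 3) -> np.ndarray:
    """Uniformly extended knot vector; n_intervals + order basis functions."""
    if hi <= lo or n_intervals < 1 or order < 0:
        raise ValueError("need hi > lo, n_intervals >= 1, order >= 0")
    h = (hi - lo) / n_intervals
    interior = np.linspace(lo, hi, n_intervals + 1)
    left = lo - h * np.arange(order, 0, -1)
    right = hi + h * np.arange(1, order + 1)
    return np.concatenate([left, interior, right])


def _basis_clamped(x: np.ndarray, knots: np.ndarray, order: int) -> np.ndarray:
    """Cox-de Boor recursion for x already inside [knots[order], knots[-order-1])."""
    x = x[..., None]
    B = ((x >= knots[:-1]) & (x < knots[1:])).astype(float)
    for d in range(1, order + 1):
        left_den = knots[d:-1] - knots[:-d - 1]
        right_den = knots[d + 1:] - knots[1:-d]
        with np.errstate(divide="ignore", invalid="ignore"):
            left = np.where(left_den > 0, (x - knots[:-d - 1]) / np.where(left_den > 0, left_den, 1.0), 0.0)
            right = np.where(right_den > 0, (knots[d + 1:] - x) / np.where(right_den > 0, right_den, 1.0), 0.0)
        B = left * B[..., :-1] + right * B[..., 1:]
    return B


def bspline_basis_and_deriv(x, knots: np.ndarray, order: int):
    """Basis values and first derivatives with linear continuation off-grid.

    For x outside [lo, hi] the returned "basis" is the first-order Taylor
    continuation B(edge) + B'(edge) * (x - edge); since the basis sums to 1
    and the derivatives sum to 0, partition of unity survives the
    continuation. Both outputs have shape x.shape + (n_basis,).
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2 * order + 2 or np.any(np.diff(knots) < 0):
        raise ValueError("malformed knot vector")
    x = np.asarray(x, dtype=float)
    lo, hi = knots[order], knots[-order - 1]
    span = hi - lo
    xc = np.clip(x, lo, hi - 1e-9 * span)   # evaluate just inside the half-open top interval
    B = _basis_clamped(xc, knots, order)
    if order == 0:
        dB = np.zeros_like(B)
    else:
        # dB_j = k * (Bm1_j / (t_{j+k}-t_j) - Bm1_{j+1} / (t_{j+k+1}-t_{j+1}))
        Bm1 = _basis_clamped(xc, knots, order - 1)
        den = knots[order:] - knots[:-order]
        term = np.where(den > 0, Bm1 / np.where(den > 0, den, 1.0), 0.0)
        dB = order * (term[..., :-1] - term[..., 1:])
    delta = (x - xc)[..., None]
    return B + dB * delta, dB


def bspline_basis(x, knots: np.ndarray, order: int) -> np.ndarray:
    """B-spline basis values (with off-grid linear continuation)."""
    return bspline_basis_and_deriv(x, knots, order)[0]


def _silu(x):
    return x / (1.0 + np.exp(-x))


def _dsilu(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


@dataclass
class SplineEdge:
    """A single edge function phi(x) = base_weight*silu(x) + sum c_m B_m(x)."""

    knots: np.ndarray
    coefficients: np.ndarray
    order: int = 3
    base_weight: float = 0.0

    def __post_init__(self) -> None:
        n_basis = len(self.knots) - self.order - 1
        if len(self.coefficients) != n_basis:
            raise ValueError(f"expected {n_basis} coefficients, got {len(self.coefficients)}")

    def __call__(self, x):
        B = bspline_basis(x, self.knots, self.order)
        return B @ self.coefficients + self.base_weight * _silu(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Layers and network
# ---------------------------------------------------------------------------

class _KANLayer:
    def __init__(self, d_in, d_out, knots, order, rng, coef_scale=0.1):
        self.knots = np.asarray(knots, dtype=float)
        self.order = int(order)
        self.d_in, self.d_out = d_in, d_out
        n_basis = len(self.knots) - self.order - 1
        self.W = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_out, d_in))
        self.C = rng.normal(0.0, coef_scale / np.sqrt(d_in), size=(d_out, d_in, n_basis))

    def edge(self, j: int, i: int) -> SplineEdge:
        return SplineEdge(self.knots, self.C[j, i].copy(), self.order, float(self.W[j, i]))

    def forward(self, X, want_cache=False):
        B, dB = bspline_basis_and_deriv(X, self.knots, self.order)  # (N, d_in, M)
        S = _silu(X)
        Y = np.einsum("nim,jim->nj", B, self.C, optimize=True) + S @ self.W.T
        if want_cache:
            return Y, (X, B, dB, S)
        return Y

    def backward(self, dY, cache):
        X, B, dB, S = cache
        gC = np.einsum("nj,nim->jim", dY, B, optimize=True)
        gW = dY.T @ S
        dX = np.einsum("nj,jim,nim->ni", dY, self.C, dB, optimize=True) + (dY @ self.W) * _dsilu(X)
        return dX, gW, gC

    def params(self):
        return [self.W, self.C]


class _Normalizer:
    """Per-feature affine map onto [-1, 1], fitted on training data only."""

    def __init__(self):
        self.lo = self.hi = None

    def fit(self, X):
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        flat = self.hi <= self.lo
        self.hi = np.where(flat, self.lo + 1.0, self.hi)   # constant feature -> maps to -1
        return self

    def transform(self, X):
        return 2.0 * (X - self.lo) / (self.hi - self.lo) - 1.0


class KANNetwork:
    """Layered KAN for regression or binary classification on tabular features.

    Parameters
    ----------
    widths : sequence of int
        Layer widths including input and output, e.g. ``[31, 8, 1]``.
    task : {"regression", "binary"}
    grid_intervals, grid_bound, order :
        Spline grid: ``grid_intervals`` uniform intervals on
        ``[-grid_bound, grid_bound]``, spline degree ``order``.
    """

    def __init__(self, widths, task="regression", grid_intervals=5, grid_bound=1.0, order=3, seed=0):
        if len(widths) < 2 or widths[-1] != 1:
            raise ValueError("widths must chain to a single output")
        if task not in ("regression", "binary"):
            raise ValueError(f"unknown task {task!r}")
        self.widths = list(widths)
        self.task = task
        rng = np.random.default_rng(seed)
        knots = uniform_knots(-grid_bound, grid_bound, grid_intervals, order)
        self.layers = [
            _KANLayer(widths[i], widths[i + 1], knots, order, rng) for i in range(len(widths) - 1)
        ]
        self.normalizer = _Normalizer()
        self.y_mean, self.y_std = 0.0, 1.0
        self._fitted = False

    # -- forward -----------------------------------------------------------
    def _raw_forward(self, Xn, want_cache=False):
        caches, H = [], Xn
        for layer in self.layers:
            if want_cache:
                H, cache = layer.forward(H, want_cache=True)
                caches.append(cache)
            else:
                H = layer.forward(H)
        return (H, caches) if want_cache else H

    def forward(self, X) -> np.ndarray:
        """Predicted days (regression) or P(positive) (binary)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.widths[0]:
            raise ValueError(f"expected (n, {self.widths[0]}) features, got {X.shape}")
        if np.isnan(X).any():
            raise ValueError("features contain missing values; impute upstream")
        Xn = self.normalizer.transform(X) if self._fitted else X
        z = self._raw_forward(Xn)[:, 0]
        if self.task == "binary":
            return 1.0 / (1.0 + np.exp(-z))
        return z * self.y_std + self.y_mean

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        state = {
            "widths": self.widths,
            "task": self.task,
            "order": self.layers[0].order,
            "knots": self.layers[0].knots.tolist(),
            "layers": [{"W": l.W.tolist(), "C": l.C.tolist()} for l in self.layers],
            "normalizer": None
            if self.normalizer.lo is None
            else {"lo": self.normalizer.lo.tolist(), "hi": self.normalizer.hi.tolist()},
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "fitted": self._fitted,
        }
        return json.dumps(state)

    @classmethod
    def from_json(cls, payload: str) -> "KANNetwork":
        state = json.loads(payload)
        net = cls.__new__(cls)
        net.widths = state["widths"]
        net.task = state["task"]
        knots = np.asarray(state["knots"])
        rng = np.random.default_rng(0)
        net.layers = []
        for i, ls in enumerate(state["layers"]):
            layer = _KANLayer(net.widths[i], net.widths[i + 1], knots, state["order"], rng)
            layer.W = np.asarray(ls["W"], dtype=float)
            layer.C = np.asarray(ls["C"], dtype=float)
            net.layers.append(layer)
        net.normalizer = _Normalizer()
        if state["normalizer"] is not None:
            net.normalizer.lo = np.asarray(state["normalizer"]["lo"], dtype=float)
            net.normalizer.hi = np.asarray(state["normalizer"]["hi"], dtype=float)
        net.y_mean, net.y_std = state["y_mean"], state["y_std"]
        net._fitted = state["fitted"]
        return net


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 0.02
    batch_size: int | None = None        # None = full batch (fully deterministic order)
    seed: int = 0
    patience: int = 100                  # early stop after this many non-improving epochs
    loss: str = "auto"                   # auto -> MSE (regression) / BCE (binary)

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.learning_rate <= 0 or self.patience <= 0:
            raise ValueError("epochs, learning rate and patience must be positive")
        if self.batch_size is not None and self.batch_size <= 0:
            raise ValueError("batch size must be positive")


@dataclass(frozen=True)
class EvalReport:
    task: str
    n: int
    mae: float | None = None
    rmse: float | None = None
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None


def _loss_and_grad(net, Xn, y):
    z, caches = net._raw_forward(Xn, want_cache=True)
    z = z[:, 0]
    n = len(y)
    if net.task == "binary":
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        dz = (p - y) / n
    else:
        resid = z - y
        loss = np.mean(resid ** 2)
        dz = 2.0 * resid / n
    if not np.isfinite(loss):
        raise TrainingDivergedError(f"non-finite loss ({loss}); lower the learning rate")
    dH = dz[:, None]
    grads = []
    for layer, cache in zip(reversed(net.layers), reversed(caches)):
        dH, gW, gC = layer.backward(dH, cache)
        grads.extend([gC, gW])
    grads.reverse()   # now ordered [W1, C1, W2, C2, ...] to match net.params()
    return float(loss), grads


def _eval_loss(net, Xn, y):
    z = net._raw_forward(Xn)[:, 0]
    if net.task == "binary":
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return float(np.mean((z - y) ** 2))


def train(net: KANNetwork, X_train, y_train, X_val, y_val, config: TrainConfig | None = None):
    """Fit the network with Adam; return (best-validation snapshot, history).

    The target is standardized internally for regression; the normalizer
    and target statistics are fitted on the training partition only. The
    returned network is the parameter snapshot from the epoch with the
    lowest validation loss, so the best-so-far validation curve in the
    history is non-increasing by construction.
    """
    config = config or TrainConfig()
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)

    net.normalizer.fit(X_train)
    net._fitted = True
    Xt = net.normalizer.transform(X_train)
    Xv = net.normalizer.transform(X_val)
    if net.task == "regression":
        net.y_mean = float(y_train.mean())
        net.y_std = float(y_train.std()) or 1.0
        yt = (y_train - net.y_mean) / net.y_std
        yv = (y_val - net.y_mean) / net.y_std
    else:
        yt, yv = y_train, y_val

    params = net.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(config.seed)

    history = {"train_loss": [], "val_loss": [], "best_epoch": 0}
    best_val, best_state, step, since_best = np.inf, None, 0, 0
    for epoch in range(config.epochs):
        if config.batch_size is None:
            batches = [np.arange(len(yt))]
        else:
            order = rng.permutation(len(yt))
            batches = [order[i:i + config.batch_size] for i in range(0, len(order), config.batch_size)]
        for idx in batches:
            _, grads = _loss_and_grad(net, Xt[idx], yt[idx])
            step += 1
            for j, (p, g) in enumerate(zip(params, grads)):
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g * g
                mhat = m[j] / (1 - beta1 ** step)
                vhat = v[j] / (1 - beta2 ** step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        tr = _eval_loss(net, Xt, yt)
        vl = _eval_loss(net, Xv, yv)
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        if vl < best_val:
            best_val, since_best = vl, 0
            best_state = [p.copy() for p in params]
            history["best_epoch"] = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        for p, b in zip(params, best_state):
            p[...] = b
    return net, history


def auc_rank(scores, labels) -> float:
    """ROC AUC by rank concordance (Mann-Whitney statistic / n_pos*n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class sample")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(labels.size, dtype=float)
    sorted_scores = scores[order]
    # midranks for ties
    i = 0
    pos = np.arange(1, labels.size + 1, dtype=float)
    while i < labels.size:
        j = i
        while j + 1 < labels.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = pos[i:j + 1].mean()
        i = j + 1
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(net: KANNetwork, X, y, threshold: float = 0.5) -> EvalReport:
    """Clinical test-set metrics: MAE/RMSE (days) or AUC/sens/spec/accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = net.forward(X)
    if net.task == "regression":
        err = preds - y
        return EvalReport(
            task="regression", n=len(y),
            mae=float(np.mean(np.abs(err))), rmse=float(np.sqrt(np.mean(err ** 2))),
        )
    labels = y.astype(int)
    auc = auc_rank(preds, labels)
    hard = (preds >= threshold).astype(int)
    tp = int(np.sum((hard == 1) & (labels == 1)))
    tn = int(np.sum((hard == 0) & (labels == 0)))
    fp = int(np.sum((hard == 1) & (labels == 0)))
    fn = int(np.sum((hard == 0) & (labels == 1)))
    return EvalReport(
        task="binary", n=len(y), auc=auc,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / len(y),
    )
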