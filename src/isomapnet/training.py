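"""Optimization protocol, cross-validation, architecture search, baselines.

Training follows a fixed protocol: Adam (lr 3e-4, beta1 0.9, beta2 0.999,
eps 1e-8), minibatches of 256 shuffled each epoch, at most 40 epochs, and
early stopping that restores the parameters of the epoch with the best
validation accuracy once accuracy has not strictly increased for 10 epochs.

Architecture search is greedy and layer-by-layer: the first hidden layer's
width is chosen from {2, 4, ..., 512} by mean 5-fold cross-validated
accuracy; each further layer is searched over widths strictly smaller than
its predecessor (re-initializing all weights per candidate) and the stack
grows only while the best score improves.  Ties break toward the smaller
width.

Two linear baselines are provided: an (optionally ridge-penalized) logistic
regression and a logistic elastic net with absolute L1/L2 penalty weights,
fitted by proximal gradient descent.
"""

from __future__ import annotations

import copy
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .annotation import RelationshipMatrix
from .netlayers import Network, NetworkSpec, LayerSpec, build_network
from .preprocess import SplitAssignment

__all__ = [
    "TrainingConfig",
    "TrainingLog",
    "SearchResult",
    "TrainingError",
    "Adam",
    "train",
    "cross_validate",
    "architecture_search",
    "WIDTH_GRID",
    "fit_logistic",
    "fit_elastic_net",
]

WIDTH_GRID: tuple[int, ...] = tuple(2 ** k for k in range(1, 10))  # 2, 4, ..., 512


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainingConfig:
    epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 0.0003
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    dropout: float = 0.2
    fsl_l1: float = 0.0005
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.patience < 1:
            raise TrainingError("epochs and patience must be >= 1")
        if self.learning_rate <= 0:
            raise TrainingError("learning rate must be positive")
        if not 0 <= self.dropout < 1:
            raise TrainingError("dropout must be in [0, 1)")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


@dataclass
class SearchResult:
    widths: list[int]
    table: dict[tuple[int, ...], float]  # candidate width stack -> mean CV accuracy
    best_score: float


class EarlyStopper:
    """Accuracy-based early stopping: strict increases reset patience, ties do not."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.since_best = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record one epoch's validation accuracy; return True when training should stop."""
        if value > self.best:
            self.best = value
            self.best_epoch = epoch
            self.since_best = 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: Sequence[np.ndarray], config: TrainingConfig):
        self.params = list(params)
        self.lr = config.learning_rate
        self.beta1, self.beta2, self.eps = config.beta1, config.beta2, config.eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _accuracy(model: Network, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((model.predict_proba(X) >= 0.5) == (y == 1)))


def train(
    model: Network,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
) -> tuple[Network, TrainingLog]:
    """Fit ``model`` in place with Adam and accuracy-based early stopping.

    Stops once validation accuracy has not strictly increased for
    ``config.patience`` epochs (ties do not reset patience) or at the epoch
    limit, and restores the parameter snapshot from the best epoch.
    Deterministic given ``config.seed``.
    """
    X, y = np.asarray(train_data[0], float), np.asarray(train_data[1], int)
    Xv, yv = np.asarray(val_data[0], float), np.asarray(val_data[1], int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), config)
    log = TrainingLog()
    stopper = EarlyStopper(config.patience)
    best_state = model.get_state()

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = model.loss_and_backward(X[idx], y[idx], rng=rng)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            epoch_loss += loss * len(idx)
            optimizer.step(model.gradients())
            if model.fsl is not None:
                model.fsl.project()
        log.train_loss.append(epoch_loss / len(y))
        val_acc = _accuracy(model, Xv, yv)
        log.val_accuracy.append(val_acc)
        log.stopped_epoch = epoch
        should_stop = stopper.update(epoch, val_acc)
        if stopper.best_epoch == epoch:  # strict improvement this epoch
            best_state = model.get_state()
        log.best_epoch = stopper.best_epoch
        if should_stop:
            break

    model.set_state(best_state)
    return model, log


def _build_for(
    spec: NetworkSpec,
    masks: Mapping[int, RelationshipMatrix] | None,
    config: TrainingConfig,
    seed: int,
) -> Network:
    spec = copy.deepcopy(spec)
    spec.dropout_rate = config.dropout
    return build_network(spec, masks=masks, seed=seed, fsl_l1=config.fsl_l1)


def cross_validate(
    spec: NetworkSpec,
    folds: SplitAssignment,
    data: tuple[np.ndarray, np.ndarray, Sequence[str]],
    config: TrainingConfig,
    masks: Mapping[int, RelationshipMatrix] | None = None,
) -> tuple[float, list[float]]:
    """Mean held-out-fold accuracy of ``spec`` across the assignment's folds.

    ``data`` is (X rows-as-samples, labels, sample_ids); only samples with a
    fold assignment participate.  Each fold's model trains on the remaining
    folds with the held-out fold doubling as the early-stopping set.
    """
    X, y, sample_ids = np.asarray(data[0], float), np.asarray(data[1], int), data[2]
    pos = {s: i for i, s in enumerate(sample_ids)}
    n_folds = folds.n_folds
    if n_folds < 2:
        raise TrainingError("fold assignment defines fewer than 2 folds")
    accs: list[float] = []
    for k in range(1, n_folds + 1):
        held = [pos[s] for s in folds.fold_samples(k) if s in pos]
        rest = [
            pos[s]
            for s, f in folds.fold.items()
            if f != k and s in pos
        ]
        if len(np.unique(y[held])) < 2 or len(np.unique(y[rest])) < 2:
            raise TrainingError(f"fold {k} lacks one of the classes")
        model = _build_for(spec, masks, config, seed=config.seed + k)
        model, _ = train(model, (X[rest], y[rest]), (X[held], y[held]), config)
        accs.append(_accuracy(model, X[held], y[held]))
    return float(np.mean(accs)), accs


def architecture_search(
    evaluator: Callable[[tuple[int, ...]], float],
    widths: Sequence[int] = WIDTH_GRID,
    max_depth: int | None = None,
) -> SearchResult:
    """Greedy layer-by-layer width search over a decreasing-width grid.

    ``evaluator`` maps a width stack (one int per hidden dense layer) to a
    score (mean CV accuracy); every candidate is evaluated from scratch, so
    earlier layers are implicitly re-initialized.  Layer 1 scans the full
    grid; layer *k+1* scans grid widths strictly below the chosen width of
    layer *k*; the stack grows only while the best score strictly improves.
    Ties break toward the smaller width (candidates are scanned ascending).
    """
    widths = sorted(widths)
    table: dict[tuple[int, ...], float] = {}
    chosen: list[int] = []
    best_score = -np.inf

    while True:
        cap = chosen[-1] if chosen else np.inf
        candidates = [w for w in widths if w < cap]
        if not candidates or (max_depth is not None and len(chosen) >= max_depth):
            break
        layer_best: tuple[int, ...] | None = None
        layer_best_score = -np.inf
        for w in candidates:  # ascending scan + strict '>' = smaller-width ties
            stack = tuple(chosen) + (w,)
            score = float(evaluator(stack))
            table[stack] = score
            if score > layer_best_score:
                layer_best_score = score
                layer_best = stack
        if layer_best is None or layer_best_score <= best_score:
            break
        best_score = layer_best_score
        chosen = list(layer_best)
    return SearchResult(widths=chosen, table=table, best_score=float(best_score))


def cv_evaluator(
    folds: SplitAssignment,
    data: tuple[np.ndarray, np.ndarray, Sequence[str]],
    config: TrainingConfig,
    input_dim: int,
    prefix_layers: Sequence[LayerSpec] = (),
    masks: Mapping[int, RelationshipMatrix] | None = None,
) -> Callable[[tuple[int, ...]], float]:
    """Build the cross-validation evaluator used by :func:`architecture_search`.

    ``prefix_layers`` (e.g. an FSL and an IML) precede the dense stack under
    search; ``masks`` are keyed by position within ``prefix_layers``.
    """

    def evaluate(stack: tuple[int, ...]) -> float:
        layers = list(copy.deepcopy(list(prefix_layers)))
        layers += [LayerSpec("dense", w) for w in stack]
        spec = NetworkSpec(input_dim=input_dim, layers=layers)
        mean, _ = cross_validate(spec, folds, data, config, masks=masks)
        return mean

    return evaluate


# ---------------------------------------------------------------------------
# Linear baselines


def _logistic_objective(
    beta: np.ndarray, X1: np.ndarray, y: np.ndarray, l2: float
) -> tuple[float, np.ndarray]:
    """Mean Bernoulli NLL + l2 * ||slopes||^2 (intercept unpenalized)."""
    z = X1 @ beta
    nll = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    grad = X1.T @ (p - y) / y.size
    if l2 > 0:
        nll += l2 * float(np.sum(beta[1:] ** 2))
        grad = grad + 2 * l2 * np.r_[0.0, beta[1:]]
    return nll, grad


def fit_logistic(
    X: np.ndarray, y: np.ndarray, l2: float = 0.0
) -> tuple[np.ndarray, float]:
    """Maximum (ridge-penalized) likelihood logistic regression.

    Optimizes to a gradient norm below 1e-8.  Returns (slopes, intercept).
    Under perfect separation with ``l2=0`` the likelihood has no maximizer;
    a warning is emitted and the current iterate returned.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise TrainingError("need both classes to fit a logistic model")
    X1 = np.column_stack([np.ones(len(y)), X])
    beta0 = np.zeros(X1.shape[1])
    res = minimize(
        _logistic_objective,
        beta0,
        args=(X1, y, l2),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 10_000, "gtol": 1e-10, "ftol": 1e-14},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > 1e-8:
        warnings.warn(
            f"logistic fit stopped with gradient norm {grad_norm:.2e} "
            "(possible perfect separation); returning current iterate",
            stacklevel=2,
        )
    return res.x[1:], float(res.x[0])


def _enet_objective(beta: np.ndarray, X1: np.ndarray, y: np.ndarray, l1: float, l2: float) -> float:
    smooth, _ = _logistic_objective(beta, X1, y, l2)
    return smooth + l1 * float(np.sum(np.abs(beta[1:])))


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    l1: float = 0.0005,
    l2: float = 0.0005,
    max_iter: int = 20_000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Logistic elastic net: mean NLL + l1*||slopes||_1 + l2*||slopes||^2.

    Fitted by proximal gradient (ISTA) with backtracking line search, so the
    objective decreases monotonically; iteration stops when the objective
    improvement falls below ``tol``.  The intercept is unpenalized.
    Returns (slopes, intercept).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise TrainingError("need both classes to fit an elastic net")
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    step = 1.0
    obj, grad = _logistic_objective(beta, X1, y, l2)
    obj += l1 * float(np.sum(np.abs(beta[1:])))
    for _ in range(max_iter):
        while True:
            cand = beta - step * grad
            # soft-threshold the slopes only
            cand[1:] = np.sign(cand[1:]) * np.maximum(np.abs(cand[1:]) - step * l1, 0.0)
            smooth_new, grad_new = _logistic_objective(cand, X1, y, l2)
            new_obj = smooth_new + l1 * float(np.sum(np.abs(cand[1:])))
            # sufficient decrease via the standard proximal upper bound
            diff = cand - beta
            smooth_old = obj - l1 * float(np.sum(np.abs(beta[1:])))
            bound = (
                smooth_old
                + float(grad @ diff)
                + float(diff @ diff) / (2 * step)
                + l1 * float(np.sum(np.abs(cand[1:])))
            )
            if new_obj <= bound + 1e-15 or step < 1e-12:
                break
            step *= 0.5
        if not np.isfinite(new_obj):
            raise TrainingError("elastic-net objective diverged")
        improved = obj - new_obj
        beta, obj, grad = cand, new_obj, grad_new
        if 0 <= improved < tol:
            break
        step = min(step * 1.5, 1e6)  # gentle step growth
    return beta[1:], float(beta[0])
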