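"""Feed-forward survival network with a proportional-hazards output layer.

The model maps a patient's expression profile ``x`` to a prognostic index
(log hazard ratio)

    theta = G(W x + b)^T beta,       G = tanh,

optionally through a second hidden layer, and is trained by maximizing the
Cox partial log-likelihood of ``theta`` with ridge and/or dropout
regularization.  With zero hidden layers the model degenerates to a standard
linear Cox-PH regression ``theta = x^T beta``, which ties the whole
machinery back to the classical model.

Everything here is plain numpy: the cost is the matrix-form partial
likelihood from :mod:`survnn.coxph`, gradients are analytic back-propagation
(checked against finite differences in the test suite), and optimization is
full-batch gradient descent with optional classical momentum or Nesterov
acceleration and a decay-on-plateau learning-rate schedule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .coxph import partial_log_likelihood, pll_gradient
from .data import SurvivalDataset, build_risk_matrix

__all__ = [
    "SurvivalNet",
    "ModelSpec",
    "TrainConfig",
    "FitResult",
    "default_hidden_size",
    "train",
    "save_model",
    "load_model",
]


def default_hidden_size(n_features: int) -> int:
    """Hidden-layer width by the square-root ("pyramid") rule of thumb."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, round(math.sqrt(n_features)))


@dataclass
class ModelSpec:
    """Architecture and regularization hyperparameters.

    ``hidden_size=None`` applies the square-root rule to the feature count.
    ``dropout_p`` is the probability of *retaining* a hidden node during a
    training iteration; 1.0 disables dropout.
    """

    n_hidden_layers: int = 1
    hidden_size: int | None = None
    dropout_p: float = 1.0
    ridge_lambda: float = 0.0
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in (0, 1, 2):
            raise ValueError("n_hidden_layers must be 0, 1 or 2")
        if not 0.0 < self.dropout_p <= 1.0:
            raise ValueError("dropout_p must be in (0, 1]")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.activation != "tanh":
            raise ValueError(f"unsupported activation {self.activation!r}")

    def resolved_hidden_size(self, n_features: int) -> int:
        return self.hidden_size if self.hidden_size is not None else default_hidden_size(n_features)


@dataclass
class TrainConfig:
    """Full-batch training schedule.

    The learning rate starts at ``learning_rate_init`` and is multiplied by
    ``lr_decay`` on every iteration whose cost fails to improve on the best
    cost seen so far.
    """

    n_iterations: int = 10000
    learning_rate_init: float = 0.1
    lr_decay: float = 0.9
    optimizer: str = "nesterov"
    momentum_coef: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.optimizer not in ("gradient", "momentum", "nesterov"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class SurvivalNet:
    """Model parameters: hidden layers ``(W_l, b_l)`` and output vector beta.

    ``weights[l]`` has shape (H_l, fan_in); ``beta`` has length H_last (or J
    for the zero-hidden-layer model).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    beta: np.ndarray
    dropout_p: float = 1.0
    ridge_lambda: float = 0.0
    activation: str = "tanh"
    feature_names: list[str] | None = None

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[1] if self.weights else self.beta.shape[0]

    def forward(
        self,
        X: np.ndarray,
        mode: str = "eval",
        masks: list[np.ndarray] | None = None,
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Prognostic index and hidden activations for a patient matrix.

        In ``train`` mode the supplied 0/1 retention masks are applied to each
        hidden layer's activations; in ``eval`` mode activations are scaled by
        the retention probability instead (weight-scaling rule), making
        evaluation deterministic.
        """
        theta, acts, _ = self._forward_cached(X, mode, masks)
        return theta, acts

    def _forward_cached(
        self,
        X: np.ndarray,
        mode: str,
        masks: list[np.ndarray] | None,
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"X must have {self.n_features} columns, got shape {X.shape}")
        if mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
        if mode == "train" and self.dropout_p < 1.0:
            if masks is None or len(masks) != self.n_hidden_layers:
                raise ValueError("train mode with dropout requires one mask per hidden layer")
        acts: list[np.ndarray] = []
        raw: list[np.ndarray] = []  # pre-mask tanh values, needed for backprop
        A = X
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            T = np.tanh(A @ W.T + b)
            raw.append(T)
            if mode == "train" and self.dropout_p < 1.0:
                A = T * masks[layer]
            elif mode == "eval" and self.dropout_p < 1.0:
                A = T * self.dropout_p
            else:
                A = T
            acts.append(A)
        theta = A @ self.beta
        return theta, acts, raw

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Prognostic index per patient (eval mode)."""
        return self.forward(X, mode="eval")[0]

    def penalty(self) -> float:
        """Ridge term: lambda * (sum of squared hidden weights + ||beta||^2)."""
        sq = float(self.beta @ self.beta) + sum(float((W * W).sum()) for W in self.weights)
        return self.ridge_lambda * sq

    def copy(self) -> "SurvivalNet":
        return SurvivalNet(
            weights=[W.copy() for W in self.weights],
            biases=[b.copy() for b in self.biases],
            beta=self.beta.copy(),
            dropout_p=self.dropout_p,
            ridge_lambda=self.ridge_lambda,
            activation=self.activation,
            feature_names=list(self.feature_names) if self.feature_names else None,
        )


def initialize_model(spec: ModelSpec, n_features: int, rng: np.random.Generator) -> SurvivalNet:
    """Seeded Glorot-uniform hidden weights, zero biases, zero beta."""
    weights, biases = [], []
    fan_in = n_features
    for _ in range(spec.n_hidden_layers):
        h = spec.resolved_hidden_size(n_features)
        bound = math.sqrt(6.0 / (fan_in + h))
        weights.append(rng.uniform(-bound, bound, size=(h, fan_in)))
        biases.append(np.zeros(h))
        fan_in = h
    beta = np.zeros(fan_in)
    return SurvivalNet(
        weights=weights,
        biases=biases,
        beta=beta,
        dropout_p=spec.dropout_p,
        ridge_lambda=spec.ridge_lambda,
        activation=spec.activation,
    )


def cost(
    model: SurvivalNet,
    X: np.ndarray,
    risk,
    event: np.ndarray,
    masks: list[np.ndarray] | None = None,
    mode: str = "train",
) -> float:
    """Regularized objective: negative partial log-likelihood + ridge."""
    theta, _ = model.forward(X, mode=mode, masks=masks)
    return -partial_log_likelihood(theta, risk, event) + model.penalty()


def cost_and_gradients(
    model: SurvivalNet,
    X: np.ndarray,
    risk,
    event: np.ndarray,
    masks: list[np.ndarray] | None = None,
    mode: str = "train",
) -> tuple[float, dict]:
    """Objective value and its analytic gradient in every parameter.

    Back-propagation through the (masked) tanh layers, starting from the
    partial-likelihood gradient in theta; the dropout mask is held fixed, so
    this is the exact gradient of the masked cost.
    """
    X = np.asarray(X, dtype=float)
    theta, acts, raw = model._forward_cached(X, mode, masks)
    c = -partial_log_likelihood(theta, risk, event) + model.penalty()
    g_theta = -pll_gradient(theta, risk, event)  # d(-pll)/d theta

    lam = model.ridge_lambda
    grads = {
        "weights": [np.empty_like(W) for W in model.weights],
        "biases": [np.empty_like(b) for b in model.biases],
        "beta": None,
    }
    A_last = acts[-1] if model.weights else X
    grads["beta"] = A_last.T @ g_theta + 2.0 * lam * model.beta

    dA = np.outer(g_theta, model.beta)  # dC/dA for the last hidden layer
    for layer in range(model.n_hidden_layers - 1, -1, -1):
        if model.dropout_p < 1.0:
            scale = masks[layer] if mode == "train" else model.dropout_p
        else:
            scale = 1.0
        delta = dA * scale * (1.0 - raw[layer] ** 2)
        below = acts[layer - 1] if layer > 0 else X
        grads["weights"][layer] = delta.T @ below + 2.0 * lam * model.weights[layer]
        grads["biases"][layer] = delta.sum(axis=0)
        if layer > 0:
            dA = delta @ model.weights[layer]
    return c, grads


def _pack(model: SurvivalNet) -> np.ndarray:
    parts = [W.ravel() for W in model.weights] + [b for b in model.biases] + [model.beta]
    return np.concatenate(parts) if parts else np.empty(0)


def _unpack_into(vec: np.ndarray, model: SurvivalNet) -> None:
    k = 0
    for i, W in enumerate(model.weights):
        model.weights[i] = vec[k : k + W.size].reshape(W.shape)
        k += W.size
    for i, b in enumerate(model.biases):
        model.biases[i] = vec[k : k + b.size]
        k += b.size
    model.beta = vec[k:]


def _pack_grads(grads: dict) -> np.ndarray:
    parts = [G.ravel() for G in grads["weights"]] + list(grads["biases"]) + [grads["beta"]]
    return np.concatenate(parts)


@dataclass
class FitResult:
    """Trained model plus its full training trace."""

    model: SurvivalNet
    loss_trace: np.ndarray
    final_pll: float
    config: TrainConfig
    spec: ModelSpec = field(default_factory=ModelSpec)


def train(ds: SurvivalDataset, spec: ModelSpec, cfg: TrainConfig) -> FitResult:
    """Fit the network on a dataset by full-batch gradient ascent on the
    regularized partial likelihood.

    Runs exactly ``cfg.n_iterations`` updates.  Each iteration draws a fresh
    per-node dropout retention mask (if ``spec.dropout_p < 1``), takes one
    plain / momentum / Nesterov step, and decays the learning rate whenever
    the iteration's cost fails to beat the best cost seen so far.
    Deterministic for a given config seed.

    Two numerical preconditioning choices (they change neither the model
    class nor the objective's optimum): inputs are standardized internally
    and the standardization is folded back into the first-layer weights of
    the returned model, and the step uses the gradient divided by the event
    count so the effective step size does not grow with cohort size.  The
    loss trace records the raw (sum-form) regularized cost.
    """
    if ds.n_events < 1:
        raise ValueError("cannot fit a survival model on data without events")
    rng = np.random.default_rng(cfg.seed)
    model = initialize_model(spec, ds.n_features, rng)
    model.feature_names = list(ds.feature_names)
    mu = ds.X.mean(axis=0)
    sd = ds.X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (ds.X - mu) / sd
    risk = build_risk_matrix(ds.time)
    event = ds.event
    n_events = float(ds.n_events)

    params = _pack(model)
    velocity = np.zeros_like(params)
    lr = cfg.learning_rate_init
    mu = cfg.momentum_coef
    best = np.inf
    trace = np.empty(cfg.n_iterations)
    use_dropout = spec.dropout_p < 1.0 and spec.n_hidden_layers > 0
    mode = "train"

    def masks_for_iteration() -> list[np.ndarray] | None:
        if not use_dropout:
            return None
        return [
            (rng.random(b.shape[0]) < spec.dropout_p).astype(float) for b in model.biases
        ]

    def eval_cost_grad(vec: np.ndarray, masks) -> tuple[float, np.ndarray]:
        _unpack_into(vec, model)
        c, grads = cost_and_gradients(model, X, risk, event, masks=masks, mode=mode)
        return c, _pack_grads(grads) / n_events

    def eval_cost(vec: np.ndarray, masks) -> float:
        _unpack_into(vec, model)
        return cost(model, X, risk, event, masks=masks, mode=mode)

    for it in range(cfg.n_iterations):
        masks = masks_for_iteration()
        if cfg.optimizer == "nesterov":
            _, g = eval_cost_grad(params + mu * velocity, masks)
            velocity = mu * velocity - lr * g
            params = params + velocity
        elif cfg.optimizer == "momentum":
            _, g = eval_cost_grad(params, masks)
            velocity = mu * velocity - lr * g
            params = params + velocity
        else:
            _, g = eval_cost_grad(params, masks)
            params = params - lr * g
        c = eval_cost(params, masks)
        if not np.isfinite(c):
            raise RuntimeError(f"training cost became non-finite at iteration {it}")
        trace[it] = c
        if c < best:
            best = c
        else:
            lr *= cfg.lr_decay
    _unpack_into(params, model)
    # fold the input standardization into the first layer so the returned
    # model operates on raw inputs; for the linear model the dropped constant
    # beta . (mu / sd) is invisible to the partial likelihood
    if model.weights:
        W0 = model.weights[0]
        model.biases[0] = model.biases[0] - W0 @ (mu / sd)
        model.weights[0] = W0 / sd[None, :]
    else:
        model.beta = model.beta / sd
    theta, _ = model.forward(ds.X, mode="eval")
    final_pll = partial_log_likelihood(theta, risk, event)
    return FitResult(model=model, loss_trace=trace, final_pll=final_pll, config=cfg, spec=spec)


# --- serialization ---------------------------------------------------------

def save_model(model: SurvivalNet, path: str, config: TrainConfig | None = None) -> None:
    """Write a model to a self-describing JSON archive (bit-exact round trip).

    Floats are stored via Python's repr, which round-trips IEEE doubles
    exactly.
    """
    payload = {
        "format": "survnn-model",
        "version": 1,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "beta": model.beta.tolist(),
        "dropout_p": model.dropout_p,
        "ridge_lambda": model.ridge_lambda,
        "activation": model.activation,
        "feature_names": model.feature_names,
        "train_config": asdict(config) if config is not None else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> SurvivalNet:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "survnn-model":
        raise ValueError(f"{path!r} is not a survnn model archive")
    return SurvivalNet(
        weights=[np.asarray(W, dtype=float) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        beta=np.asarray(payload["beta"], dtype=float),
        dropout_p=payload["dropout_p"],
        ridge_lambda=payload["ridge_lambda"],
        activation=payload["activation"],
        feature_names=payload["feature_names"],
    )
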