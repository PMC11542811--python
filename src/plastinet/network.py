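"""Two-layer perceptron: forward pass, per-sample backprop proposals, evaluation.

The network is 784-N_h-10 shaped in the reference setting: a single hidden
layer of leaky-rectifying units (slope 1 for non-negative net input, ``beta``
otherwise) and linear output units trained on mean squared error.  Both layers
carry a bias, represented as a synapse from a constant-1 input so that biases
participate in masking and energy accounting like any other synapse.

``backprop_proposal`` computes the raw weight-change proposal
``dW = -lr * outer(delta, input)`` without applying it; restriction operators
(see :mod:`plastinet.strategies`) and the caching rule
(:mod:`plastinet.caching`) decide what is actually applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ShapeError(ValueError):
    """Raised when arrays passed to network operations have inconsistent shapes."""


@dataclass
class MLPWeights:
    """Weights of the two-layer network.

    ``W_in`` has shape ``(N_h, n_in + 1)`` and ``W_out`` shape
    ``(n_out, N_h + 1)``; the last column of each is the bias weight.
    """

    W_in: np.ndarray
    W_out: np.ndarray
    beta: float = 0.1
    activation_variant: str = "lrelu"
    output_variant: str = "linear_mse"

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=np.float64)
        self.W_out = np.asarray(self.W_out, dtype=np.float64)
        if self.W_in.ndim != 2 or self.W_out.ndim != 2:
            raise ShapeError("weight arrays must be 2-D")
        if self.W_out.shape[1] != self.W_in.shape[0] + 1:
            raise ShapeError(
                f"W_out expects {self.W_in.shape[0] + 1} columns, got {self.W_out.shape[1]}"
            )
        if self.activation_variant not in ("lrelu", "relu"):
            raise ValueError(f"unknown activation_variant {self.activation_variant!r}")
        if self.output_variant not in ("linear_mse", "softmax_ce"):
            raise ValueError(f"unknown output_variant {self.output_variant!r}")

    @property
    def n_in(self) -> int:
        return self.W_in.shape[1] - 1

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]

    @property
    def n_out(self) -> int:
        return self.W_out.shape[0]

    @property
    def n_synapses(self) -> int:
        """Total synapse count, biases included."""
        return self.W_in.size + self.W_out.size

    @property
    def _leak(self) -> float:
        return self.beta if self.activation_variant == "lrelu" else 0.0

    def copy(self) -> "MLPWeights":
        return MLPWeights(
            self.W_in.copy(), self.W_out.copy(), self.beta, self.activation_variant, self.output_variant
        )


@dataclass
class ForwardTrace:
    """Per-sample activations recorded during the forward pass."""

    h_hidden: np.ndarray  # net input to hidden units
    a_hidden: np.ndarray  # hidden activations g(h)
    y: np.ndarray  # network outputs


@dataclass
class UpdateProposal:
    """Raw backprop weight-change proposal, before any restriction."""

    dW_in: np.ndarray
    dW_out: np.ndarray
    learning_rate: float


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of per-sample SGD training to an accuracy criterion."""

    learning_rate: float = 0.01
    init_sd: float = 0.01
    criterion_accuracy: float = 0.95
    eval_every: int = 1000
    max_epochs: int = 50
    seed: int = 0
    activation_variant: str = "lrelu"
    output_variant: str = "linear_mse"
    beta: float = 0.1
    zero_mean_inputs: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.criterion_accuracy <= 1):
            raise ValueError("criterion_accuracy must lie in (0, 1]")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")


def init_weights(
    n_in: int,
    n_hidden: int,
    n_out: int,
    init_sd: float = 0.01,
    rng: np.random.Generator | None = None,
    beta: float = 0.1,
    activation_variant: str = "lrelu",
    output_variant: str = "linear_mse",
) -> MLPWeights:
    """Independent Gaussian initialization (sd ``init_sd``), biases included."""
    rng = rng or np.random.default_rng()
    return MLPWeights(
        rng.normal(0.0, init_sd, size=(n_hidden, n_in + 1)),
        rng.normal(0.0, init_sd, size=(n_out, n_hidden + 1)),
        beta=beta,
        activation_variant=activation_variant,
        output_variant=output_variant,
    )


def _augment(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x, np.ones(1)])


def _softmax(h: np.ndarray) -> np.ndarray:
    z = np.exp(h - h.max())
    return z / z.sum()


def forward(weights: MLPWeights, x: np.ndarray, x_aug: np.ndarray | None = None) -> ForwardTrace:
    """Single-sample forward pass.

    ``x_aug`` may supply the pre-augmented input ``(x, 1)`` to avoid a copy in
    tight training loops.
    """
    if x_aug is None:
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (weights.n_in,):
            raise ShapeError(f"input has shape {x.shape}, expected ({weights.n_in},)")
        x_aug = _augment(x)
    h = weights.W_in @ x_aug
    leak = weights._leak
    a = np.where(h >= 0, h, leak * h)
    y = weights.W_out @ _augment(a)
    if weights.output_variant == "softmax_ce":
        y = _softmax(y)
    return ForwardTrace(h_hidden=h, a_hidden=a, y=y)


def backprop_proposal(
    weights: MLPWeights,
    trace: ForwardTrace,
    x: np.ndarray,
    target: np.ndarray,
    learning_rate: float,
    x_aug: np.ndarray | None = None,
) -> UpdateProposal:
    """Raw per-sample backprop proposal ``dW = -lr * outer(delta, input)``.

    Output error is ``y - t`` (linear outputs under MSE; softmax outputs under
    cross-entropy give the same expression).  Hidden error is the
    back-propagated error scaled by the activation derivative.
    """
    if x_aug is None:
        x_aug = _augment(np.asarray(x, dtype=np.float64))
    if trace.a_hidden.shape != (weights.n_hidden,) or x_aug.shape != (weights.n_in + 1,):
        raise ShapeError("trace/input inconsistent with weights")
    target = np.asarray(target, dtype=np.float64)
    d_out = trace.y - target
    leak = weights._leak
    gprime = np.where(trace.h_hidden >= 0, 1.0, leak)
    d_hid = gprime * (weights.W_out[:, :-1].T @ d_out)
    dW_out = -learning_rate * np.outer(d_out, _augment(trace.a_hidden))
    dW_in = -learning_rate * np.outer(d_hid, x_aug)
    return UpdateProposal(dW_in=dW_in, dW_out=dW_out, learning_rate=learning_rate)


def apply_update(weights: MLPWeights, restricted: UpdateProposal) -> UpdateProposal:
    """Add the (restricted) proposal to the weights in place.

    Returns the proposal itself: the actually-applied deltas, for energy
    charging.
    """
    if restricted.dW_in.shape != weights.W_in.shape or restricted.dW_out.shape != weights.W_out.shape:
        raise ShapeError("proposal shapes do not match weights")
    if not (np.isfinite(restricted.dW_in).all() and np.isfinite(restricted.dW_out).all()):
        raise FloatingPointError("non-finite entries in update proposal")
    weights.W_in += restricted.dW_in
    weights.W_out += restricted.dW_out
    return restricted


def batch_outputs(weights: MLPWeights, features: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over a feature matrix; returns outputs (n, n_out)."""
    X = np.asarray(features, dtype=np.float64)
    H = X @ weights.W_in[:, :-1].T + weights.W_in[:, -1]
    leak = weights._leak
    A = np.where(H >= 0, H, leak * H)
    Y = A @ weights.W_out[:, :-1].T + weights.W_out[:, -1]
    if weights.output_variant == "softmax_ce":
        Z = np.exp(Y - Y.max(axis=1, keepdims=True))
        Y = Z / Z.sum(axis=1, keepdims=True)
    return Y


def evaluate_accuracy(weights: MLPWeights, dataset) -> float:
    """Fraction of samples whose argmax output matches the label (ties: lowest index)."""
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")
    pred = np.argmax(batch_outputs(weights, dataset.features), axis=1)
    return float(np.mean(pred == dataset.labels))


def save_weights(path, weights: MLPWeights) -> None:
    """Serialize weights to a single ``.npz`` container with a metadata block."""
    np.savez(
        path,
        W_in=weights.W_in,
        W_out=weights.W_out,
        meta=np.array(
            [weights.beta, float(weights.activation_variant == "relu"), float(weights.output_variant == "softmax_ce")]
        ),
    )


def load_weights(path) -> MLPWeights:
    with np.load(path) as data:
        beta, is_relu, is_softmax = data["meta"]
        return MLPWeights(
            data["W_in"],
            data["W_out"],
            beta=float(beta),
            activation_variant="relu" if is_relu else "lrelu",
            output_variant="softmax_ce" if is_softmax else "linear_mse",
        )
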