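"""Minimal feedforward network with online backpropagation.

This module implements the computational substrate of the simulation: a
three-layer (input -> hidden -> output) fully connected network with
logistic-sigmoid activations, a single output unit, and incremental
(per-trial) gradient-descent training on the squared output error.  The
stopping rule is a root-mean-square error criterion evaluated over the whole
training table with learning disabled.

The module is deliberately encoding-blind: it operates on binary input
vectors and scalar 0/1 targets only, and knows nothing about stimuli,
compounds or experimental phases.  Those live in :mod:`gonogonet.protocol`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TrainingConfig",
    "Network",
    "TrainingTrace",
    "init_network",
    "forward",
    "forward_batch",
    "backprop_step",
    "compute_rms",
    "train_to_criterion",
    "loss",
    "finite_difference_gradients",
    "analytic_gradients",
    "gradient_check",
    "save_weights",
    "load_weights",
]

# Sentinel for "did not reach criterion within max_epochs"
NOT_CONVERGED = -1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the online backpropagation trainer.

    Defaults are the simulation conditions of the original go/no-go
    experiments: learning rate 0.3, zero momentum, uniform weight
    initialization on [0, 1), and stopping when the root-mean-square output
    error over the training table falls to 0.0025 or below.
    """

    learning_rate: float = 0.3
    momentum: float = 0.0
    rms_threshold: float = 0.0025
    max_epochs: int = 100_000
    init_low: float = 0.0
    init_high: float = 1.0
    shuffle_each_epoch: bool = False
    #: "mse" stops on the mean squared error over the training table (the
    #: readout FANN-style libraries report and the reading under which the
    #: published epoch counts are reproducible); "rms" stops on its square
    #: root.
    criterion_metric: str = "mse"
    #: Update regime: "incremental" applies a weight update after every
    #: trial; "batch" accumulates gradients over the epoch and applies one
    #: summed update at its end.
    update_mode: str = "incremental"
    use_bias: bool = True
    steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.momentum < 0:
            raise ValueError("momentum must be non-negative")
        if self.rms_threshold <= 0:
            raise ValueError("rms_threshold must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not self.init_low < self.init_high:
            raise ValueError(
                f"init_low ({self.init_low}) must be strictly below "
                f"init_high ({self.init_high})"
            )
        if self.criterion_metric not in ("rms", "mse"):
            raise ValueError("criterion_metric must be 'rms' or 'mse'")
        if self.update_mode not in ("incremental", "batch"):
            raise ValueError("update_mode must be 'incremental' or 'batch'")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


@dataclass
class Network:
    """Weights of a three-layer feedforward network with one output unit.

    ``w_ih`` has shape ``(n_inputs + 1, n_hidden)`` and ``w_ho`` shape
    ``(n_hidden + 1,)``; the final row/entry is the bias weight.  When
    ``use_bias`` is false the bias weights are held at zero and excluded
    from training, so the shapes never change.  ``v_ih``/``v_ho`` hold the
    previous weight change for the momentum term.
    """

    w_ih: np.ndarray
    w_ho: np.ndarray
    steepness: float = 1.0
    use_bias: bool = True
    v_ih: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    v_ho: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float).reshape(-1)
        if self.w_ih.ndim != 2:
            raise ValueError("w_ih must be a 2-D array")
        if self.w_ih.shape[1] + 1 != self.w_ho.shape[0]:
            raise ValueError(
                f"inconsistent shapes: w_ih {self.w_ih.shape} implies "
                f"{self.w_ih.shape[1]} hidden units but w_ho has "
                f"{self.w_ho.shape[0] - 1}"
            )
        if not (np.isfinite(self.w_ih).all() and np.isfinite(self.w_ho).all()):
            raise ValueError("weights must be finite")
        if self.v_ih is None:
            self.v_ih = np.zeros_like(self.w_ih)
        if self.v_ho is None:
            self.v_ho = np.zeros_like(self.w_ho)

    @property
    def n_inputs(self) -> int:
        return self.w_ih.shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    def copy(self) -> "Network":
        return Network(
            self.w_ih.copy(),
            self.w_ho.copy(),
            self.steepness,
            self.use_bias,
            self.v_ih.copy(),
            self.v_ho.copy(),
        )


@dataclass(frozen=True)
class TrainingTrace:
    """Record of one training phase."""

    epochs_to_criterion: int
    iterations_to_criterion: int
    rms_history: tuple
    converged: bool


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    # Clipping keeps exp() finite for extreme pre-activations; the output
    # remains strictly inside (0, 1) in float64.
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def init_network(
    n_inputs: int,
    n_hidden: int,
    config: TrainingConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Network:
    """Create a network with weights drawn uniformly from [init_low, init_high)."""
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError(
            f"layer sizes must be positive, got n_inputs={n_inputs}, "
            f"n_hidden={n_hidden}"
        )
    config = config or TrainingConfig()
    rng = np.random.default_rng(rng)
    w_ih = rng.uniform(config.init_low, config.init_high, size=(n_inputs + 1, n_hidden))
    w_ho = rng.uniform(config.init_low, config.init_high, size=n_hidden + 1)
    if not config.use_bias:
        w_ih[-1, :] = 0.0
        w_ho[-1] = 0.0
    return Network(w_ih, w_ho, steepness=config.steepness, use_bias=config.use_bias)


def _check_input(net: Network, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(
            f"input vector has length {x.shape}, network expects {net.n_inputs}"
        )
    return x


def _forward_parts(net: Network, x: np.ndarray):
    """Forward pass returning (hidden activations, output activation)."""
    bias = 1.0 if net.use_bias else 0.0
    h = _sigmoid(net.steepness * (x @ net.w_ih[:-1] + bias * net.w_ih[-1]))
    y = _sigmoid(net.steepness * (h @ net.w_ho[:-1] + bias * net.w_ho[-1]))
    return h, float(y)


def forward(net: Network, x: Sequence[float] | np.ndarray) -> float:
    """Propagate one input vector; returns the output activation in (0, 1)."""
    x = _check_input(net, np.asarray(x, dtype=float))
    return _forward_parts(net, x)[1]


def forward_batch(net: Network, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise ValueError(
            f"input matrix has {X.shape[1]} columns, network expects {net.n_inputs}"
        )
    bias = 1.0 if net.use_bias else 0.0
    H = _sigmoid(net.steepness * (X @ net.w_ih[:-1] + bias * net.w_ih[-1]))
    return np.asarray(
        _sigmoid(net.steepness * (H @ net.w_ho[:-1] + bias * net.w_ho[-1]))
    )


def loss(net: Network, x: np.ndarray, target: float) -> float:
    """Squared-error loss 0.5 * (output - target)^2 for one trial."""
    return 0.5 * (forward(net, x) - target) ** 2


def analytic_gradients(net: Network, x: np.ndarray, target: float):
    """Backpropagated gradients of :func:`loss` w.r.t. ``w_ih`` and ``w_ho``."""
    x = _check_input(net, np.asarray(x, dtype=float))
    bias = 1.0 if net.use_bias else 0.0
    h, y = _forward_parts(net, x)
    h_aug = np.append(h, bias)
    x_aug = np.append(x, bias)

    delta_o = (y - target) * net.steepness * y * (1.0 - y)
    g_ho = delta_o * h_aug
    delta_h = delta_o * net.w_ho[:-1] * net.steepness * h * (1.0 - h)
    g_ih = np.outer(x_aug, delta_h)
    return g_ih, g_ho


def backprop_step(
    net: Network,
    x: Sequence[float] | np.ndarray,
    target: float,
    config: TrainingConfig,
) -> float:
    """One online gradient-descent update on a single trial, in place.

    The weight change is the classic momentum rule
    ``dw(t) = -lr * grad + momentum * dw(t-1)`` (inert at momentum = 0).
    Returns the squared error of the trial before the update.
    """
    x = _check_input(net, np.asarray(x, dtype=float))
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target must lie in [0, 1], got {target!r}")
    g_ih, g_ho = analytic_gradients(net, x, target)
    err = float(forward(net, x) - target)

    net.v_ih = -config.learning_rate * g_ih + config.momentum * net.v_ih
    net.v_ho = -config.learning_rate * g_ho + config.momentum * net.v_ho
    if not net.use_bias:
        net.v_ih[-1, :] = 0.0
        net.v_ho[-1] = 0.0
    net.w_ih += net.v_ih
    net.w_ho += net.v_ho
    return err * err


def compute_rms(
    net: Network,
    X: np.ndarray,
    targets: np.ndarray,
    metric: str = "rms",
) -> float:
    """Error of the current weights over a trial table, learning disabled.

    ``metric="rms"`` returns sqrt(mean (output - target)^2); ``"mse"``
    returns the mean squared error itself.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    targets = np.asarray(targets, dtype=float).reshape(-1)
    if X.shape[0] == 0:
        raise ValueError("trial set must be non-empty")
    if X.shape[0] != targets.shape[0]:
        raise ValueError("X and targets disagree on the number of trials")
    mse = float(np.mean((forward_batch(net, X) - targets) ** 2))
    if metric == "rms":
        return float(np.sqrt(mse))
    if metric == "mse":
        return mse
    raise ValueError("metric must be 'rms' or 'mse'")


def train_to_criterion(
    net: Network,
    X: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator | int | None = None,
) -> TrainingTrace:
    """Train ``net`` in place until the stopping criterion is met.

    One epoch is one pass over all trials (fixed table order unless
    ``config.shuffle_each_epoch``).  After each epoch the criterion metric
    is evaluated over the full table with learning disabled; training stops
    once it is at or below ``config.rms_threshold``, or at
    ``config.max_epochs``, in which case the trace is flagged as
    non-convergent (no exception is raised).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    targets = np.asarray(targets, dtype=float).reshape(-1)
    if X.shape[0] == 0:
        raise ValueError("trial set must be non-empty")
    rng = np.random.default_rng(rng)
    n_trials = X.shape[0]

    history: list[float] = []
    err0 = compute_rms(net, X, targets, config.criterion_metric)
    if err0 <= config.rms_threshold:
        # Already at criterion: zero additional epochs needed.
        return TrainingTrace(0, 0, (err0,), True)

    converged = False
    epochs = 0
    # Inlined per-trial update (same arithmetic as backprop_step) keeps the
    # epoch loop fast enough for thousands of epochs per run.
    bias = 1.0 if net.use_bias else 0.0
    st = net.steepness
    lr = config.learning_rate
    mom = config.momentum
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_trials) if config.shuffle_each_epoch else range(n_trials)
        if config.update_mode == "incremental":
            for i in order:
                xi = X[i]
                ti = targets[i]
                h = _sigmoid(st * (xi @ net.w_ih[:-1] + bias * net.w_ih[-1]))
                y = _sigmoid(st * (h @ net.w_ho[:-1] + bias * net.w_ho[-1]))
                delta_o = (y - ti) * st * y * (1.0 - y)
                delta_h = delta_o * net.w_ho[:-1] * st * h * (1.0 - h)
                x_aug = np.append(xi, bias)
                net.v_ih = -lr * np.outer(x_aug, delta_h) + mom * net.v_ih
                g_ho = delta_o * np.append(h, bias)
                net.v_ho = -lr * g_ho + mom * net.v_ho
                if not net.use_bias:
                    net.v_ih[-1, :] = 0.0
                    net.v_ho[-1] = 0.0
                net.w_ih += net.v_ih
                net.w_ho += net.v_ho
        else:
            g_ih = np.zeros_like(net.w_ih)
            g_ho = np.zeros_like(net.w_ho)
            for i in order:
                gi, go = analytic_gradients(net, X[i], targets[i])
                g_ih += gi
                g_ho += go
            net.v_ih = -config.learning_rate * g_ih + config.momentum * net.v_ih
            net.v_ho = -config.learning_rate * g_ho + config.momentum * net.v_ho
            if not net.use_bias:
                net.v_ih[-1, :] = 0.0
                net.v_ho[-1] = 0.0
            net.w_ih += net.v_ih
            net.w_ho += net.v_ho
        err = compute_rms(net, X, targets, config.criterion_metric)
        history.append(err)
        epochs = epoch
        if err <= config.rms_threshold:
            converged = True
            break

    return TrainingTrace(
        epochs_to_criterion=epochs if converged else NOT_CONVERGED,
        iterations_to_criterion=epochs * n_trials if converged else NOT_CONVERGED,
        rms_history=tuple(history),
        converged=converged,
    )


def finite_difference_gradients(
    net: Network, x: np.ndarray, target: float, eps: float = 1e-6
):
    """Central finite-difference gradients of :func:`loss`.

    Independent numerical oracle for the backpropagated gradients: every
    weight is perturbed by ±eps and the loss difference quotient taken.
    """
    x = np.asarray(x, dtype=float)
    g_ih = np.zeros_like(net.w_ih)
    g_ho = np.zeros_like(net.w_ho)
    probe = net.copy()
    for idx in np.ndindex(net.w_ih.shape):
        orig = probe.w_ih[idx]
        probe.w_ih[idx] = orig + eps
        up = loss(probe, x, target)
        probe.w_ih[idx] = orig - eps
        down = loss(probe, x, target)
        probe.w_ih[idx] = orig
        g_ih[idx] = (up - down) / (2 * eps)
    for j in range(net.w_ho.shape[0]):
        orig = probe.w_ho[j]
        probe.w_ho[j] = orig + eps
        up = loss(probe, x, target)
        probe.w_ho[j] = orig - eps
        down = loss(probe, x, target)
        probe.w_ho[j] = orig
        g_ho[j] = (up - down) / (2 * eps)
    return g_ih, g_ho


def gradient_check(
    n_triples: int = 100,
    n_inputs: int = 6,
    n_hidden: int = 5,
    eps: float = 1e-6,
    seed: int | None = 0,
) -> float:
    """Max relative error between backprop and finite-difference gradients.

    Draws ``n_triples`` random (network, input, target) triples and compares
    :func:`analytic_gradients` against :func:`finite_difference_gradients`.
    Bias-disabled weights (held at zero) are excluded from the comparison.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_triples):
        cfg = TrainingConfig(init_low=-1.0, init_high=1.0)
        net = init_network(n_inputs, n_hidden, cfg, rng)
        x = rng.integers(0, 2, size=n_inputs).astype(float)
        target = float(rng.integers(0, 2))
        a_ih, a_ho = analytic_gradients(net, x, target)
        f_ih, f_ho = finite_difference_gradients(net, x, target, eps)
        for a, f in ((a_ih, f_ih), (a_ho, f_ho)):
            denom = np.maximum(np.abs(a) + np.abs(f), 1e-8)
            worst = max(worst, float(np.max(np.abs(a - f) / denom)))
    return worst


def save_weights(net: Network, path) -> None:
    """Write a plain-text weight snapshot.

    Layout: a header line ``# gonogonet weights n_inputs=<i> n_hidden=<h>
    steepness=<s> use_bias=<0|1>``, then the (n_inputs+1) x n_hidden
    input->hidden matrix row-major, one row per line, then one line with the
    (n_hidden+1) hidden->output weights.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# gonogonet weights n_inputs={net.n_inputs} "
            f"n_hidden={net.n_hidden} steepness={net.steepness!r} "
            f"use_bias={int(net.use_bias)}\n"
        )
        for row in net.w_ih:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
        fh.write(" ".join(f"{v:.17g}" for v in net.w_ho) + "\n")


def load_weights(path) -> Network:
    """Read a snapshot written by :func:`save_weights`."""
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(
            kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
        )
        n_inputs = int(fields["n_inputs"])
        n_hidden = int(fields["n_hidden"])
        rows = [
            [float(v) for v in line.split()] for line in fh if line.strip()
        ]
    w_ih = np.array(rows[: n_inputs + 1])
    w_ho = np.array(rows[n_inputs + 1])
    if w_ih.shape != (n_inputs + 1, n_hidden) or w_ho.shape != (n_hidden + 1,):
        raise ValueError(f"weight file {path} is inconsistent with its header")
    return Network(
        w_ih,
        w_ho,
        steepness=float(fields.get("steepness", 1.0)),
        use_bias=bool(int(fields.get("use_bias", 1))),
    )
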