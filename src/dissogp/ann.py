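"""Multilayer perceptron with per-pattern backpropagation training.

The trainer reproduces the study's algorithmic recipe rather than a
textbook batch optimiser:

* **online updates** — the epoch size is one: each epoch draws a single
  random training record and performs one weight update;
* **momentum** with factor 0.3;
* **delta-bar-delta** per-weight adaptive learning rates, initial rate
  0.65: a weight whose gradient keeps its sign against an exponential
  gradient trace gains rate additively, a sign flip decays it
  multiplicatively, so every weight keeps a strictly positive rate;
* **jog-of-weights** — when the training error has not improved for a
  patience window (default 100,000 epochs), uniform noise is added to all
  weights and the patience counter resets, a cheap escape from local
  minima;
* **stop-point snapshots** — weight copies with train (and optionally
  held-out) RMSE are captured at a schedule of epoch counts so the most
  general snapshot can be selected afterwards.

All randomness flows from the config seed; training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .metrics import rmse

__all__ = [
    "STOP_POINTS",
    "ACTIVATIONS",
    "MLPConfig",
    "MLPModel",
    "Snapshot",
    "TrainingTrace",
    "mlp_forward",
    "mlp_train",
    "train_on_dataset",
    "select_best_snapshot",
    "TrainingDomainError",
]

#: The study's epoch-count snapshot schedule.
STOP_POINTS = (5_000, 10_000, 15_000, 20_000, 30_000, 50_000, 100_000,
               150_000, 200_000, 300_000, 500_000, 750_000, 1_000_000)


def _fsr(a):
    # "logarithmic (fsr)" transfer: odd, unbounded, logarithmic growth
    return np.sign(a) * np.log1p(np.abs(a))


def _fsr_prime(a):
    return 1.0 / (1.0 + np.abs(a))


def _logistic(a):
    return 1.0 / (1.0 + np.exp(-a))


ACTIVATIONS = {
    "linear": (lambda a: a, lambda a: np.ones_like(a), (-np.inf, np.inf)),
    "logistic": (_logistic, lambda a: _logistic(a) * (1.0 - _logistic(a)), (0.0, 1.0)),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2, (-1.0, 1.0)),
    "fsr": (_fsr, _fsr_prime, (-np.inf, np.inf)),
}


class TrainingDomainError(ValueError):
    """Targets fall outside the activation's output range; scale first."""


@dataclass
class MLPConfig:
    """Architecture and training hyper-parameters.

    ``hidden_layout`` lists hidden-layer widths (the study swept 1-7 hidden
    layers); the output is always a single unit (MISO) sharing the hidden
    activation.  Delta-bar-delta constants (kappa, phi, trace decay) follow
    Jacobs' formulation and are exposed because the study does not state
    them.  ``eval_interval`` controls how often (in epochs) the train RMSE
    is refreshed for the patience test.
    """

    hidden_layout: tuple = (5,)
    activation: str = "tanh"
    momentum: float = 0.3
    lr_init: float = 0.65
    patience_epochs: int = 100_000
    stop_points: tuple = STOP_POINTS
    max_epochs: int = 1_000_000
    seed: int = 0
    dbd_kappa: float = 0.01
    dbd_phi: float = 0.9
    dbd_decay: float = 0.7
    jog_rel: float = 0.1
    jog_abs: float = 0.01
    patience_tol: float = 0.0  # min RMSE drop that counts as improvement
    eval_interval: int = 1_000

    def __post_init__(self):
        self.hidden_layout = tuple(int(w) for w in self.hidden_layout)
        if any(w < 1 for w in self.hidden_layout) or not self.hidden_layout:
            raise ValueError("hidden layer widths must be >= 1")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.lr_init <= 0:
            raise ValueError("initial learning rate must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.stop_points = tuple(sorted(int(s) for s in self.stop_points
                                        if s <= self.max_epochs))


@dataclass
class MLPModel:
    """Trained (or initial) network: per-layer weights and biases."""

    weights: list  # [(W (n_out, n_in), b (n_out,)) ...]
    config: MLPConfig
    epochs_trained: int = 0

    @property
    def n_inputs(self) -> int:
        return self.weights[0][0].shape[1]

    def forward(self, X):
        """Batch forward pass; X shape (n, n_inputs) -> y shape (n,)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        f, _, _ = ACTIVATIONS[self.config.activation]
        h = X
        for W, b in self.weights:
            h = f(h @ W.T + b)
        return h[:, 0]

    def input_jacobian(self, X):
        """Exact d(output)/d(input) for every record; shape (n, n_inputs)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        f, fprime, _ = ACTIVATIONS[self.config.activation]
        h = X
        pre = []
        for W, b in self.weights:
            a = h @ W.T + b
            pre.append(a)
            h = f(a)
        # chain rule backwards: J_l = diag(f'(a_l)) W_l
        G = fprime(pre[-1])[:, :, None] * self.weights[-1][0][None, :, :]
        for a, (W, _) in zip(reversed(pre[:-1]), reversed(self.weights[:-1])):
            G = (G * fprime(a)[:, None, :]) @ W
        return G[:, 0, :]

    def to_json(self) -> str:
        return json.dumps({
            "config": {**self.config.__dict__,
                       "hidden_layout": list(self.config.hidden_layout),
                       "stop_points": list(self.config.stop_points)},
            "epochs_trained": self.epochs_trained,
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        raw = json.loads(text)
        cfg = MLPConfig(**raw["config"])
        weights = [(np.array(W, dtype=float), np.array(b, dtype=float))
                   for W, b in raw["weights"]]
        return cls(weights, cfg, raw["epochs_trained"])


def mlp_forward(model: MLPModel, x):
    """Feed-forward value for a single input vector."""
    return float(model.forward(np.asarray(x, dtype=float)[None, :])[0])


@dataclass
class Snapshot:
    epoch: int
    weights: list
    train_rmse: float
    test_rmse: float | None = None


@dataclass
class TrainingTrace:
    """Stop-point snapshots and jog-of-weights event log."""

    snapshots: list = field(default_factory=list)
    jog_epochs: list = field(default_factory=list)
    config: MLPConfig | None = None


def _init_weights(n_inputs: int, cfg: MLPConfig, rng) -> list:
    widths = [n_inputs, *cfg.hidden_layout, 1]
    out = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(n_in)
        out.append((rng.uniform(-bound, bound, size=(n_out, n_in)),
                    rng.uniform(-bound, bound, size=n_out)))
    return out


def mlp_train(X, y, cfg: MLPConfig,
              X_test=None, y_test=None) -> tuple[MLPModel, TrainingTrace]:
    """Train a MISO perceptron with the study's online algorithm.

    X: (n, m) inputs, y: (n,) targets — both already scaled into the
    activation's output/input working range.  Returns the final-epoch model
    and the trace of stop-point snapshots (each holding an independent
    weight copy plus train and, when a test set is given, held-out RMSE).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y) or len(y) == 0:
        raise ValueError("X and y must be nonempty and paired")
    _, _, (lo, hi) = ACTIVATIONS[cfg.activation]
    if y.min() < lo or y.max() > hi:
        raise TrainingDomainError(
            f"targets in [{y.min():.3g}, {y.max():.3g}] exceed the "
            f"{cfg.activation} output range ({lo}, {hi}); scale the data first"
        )
    if X_test is not None:
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        y_test = np.asarray(y_test, dtype=float).ravel()

    rng = np.random.default_rng(cfg.seed)
    f, fprime, _ = ACTIVATIONS[cfg.activation]
    weights = _init_weights(X.shape[1], cfg, rng)
    lr = [(np.full_like(W, cfg.lr_init), np.full_like(b, cfg.lr_init))
          for W, b in weights]
    trace_g = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]

    model = MLPModel(weights, cfg)
    trace = TrainingTrace(config=cfg)
    stop_set = set(cfg.stop_points)
    best_rmse, best_epoch = np.inf, 0
    n = len(y)

    for epoch in range(1, cfg.max_epochs + 1):
        i = int(rng.integers(n))
        # forward, keeping pre-activations
        h = X[i]
        acts, pres = [h], []
        for W, b in weights:
            a = W @ h + b
            pres.append(a)
            h = f(a)
            acts.append(h)
        err = h[0] - y[i]
        # backward
        delta = err * fprime(pres[-1])
        for li in range(len(weights) - 1, -1, -1):
            W, b = weights[li]
            gW = np.outer(delta, acts[li])
            gb = delta
            if li > 0:
                delta = (W.T @ delta) * fprime(pres[li - 1])
            for g, slot in ((gW, 0), (gb, 1)):
                rate = lr[li][slot]
                tr = trace_g[li][slot]
                s = g * tr
                rate[s > 0] += cfg.dbd_kappa
                rate[s < 0] *= cfg.dbd_phi
                tr *= cfg.dbd_decay
                tr += (1.0 - cfg.dbd_decay) * g
                v = vel[li][slot]
                v *= cfg.momentum
                v -= rate * g
            W += vel[li][0]
            b += vel[li][1]

        if epoch % cfg.eval_interval == 0 or epoch in stop_set:
            train_rmse = rmse(y, model.forward(X))
            if train_rmse < best_rmse - cfg.patience_tol:
                best_rmse, best_epoch = train_rmse, epoch
            if epoch in stop_set:
                test_rmse = (rmse(y_test, model.forward(X_test))
                             if X_test is not None else None)
                trace.snapshots.append(Snapshot(
                    epoch, [(W.copy(), b.copy()) for W, b in weights],
                    train_rmse, test_rmse))
            if epoch - best_epoch >= cfg.patience_epochs:
                for W, b in weights:
                    for w in (W, b):
                        amp = np.maximum(cfg.jog_rel * np.abs(w), cfg.jog_abs)
                        w += rng.uniform(-1.0, 1.0, size=w.shape) * amp
                trace.jog_epochs.append(epoch)
                best_rmse, best_epoch = np.inf, epoch

    model.epochs_trained = cfg.max_epochs
    return model, trace


def train_on_dataset(ds, cfg: MLPConfig,
                     inputs=("d_mm", "t_min"), output="Q_pct",
                     test=None) -> tuple[MLPModel, TrainingTrace]:
    """Convenience wrapper: train on dataset columns (already scaled)."""
    X = ds.df.loc[:, list(inputs)].to_numpy(dtype=float)
    y = ds.df[output].to_numpy(dtype=float)
    if test is not None:
        return mlp_train(X, y, cfg,
                         test.df.loc[:, list(inputs)].to_numpy(dtype=float),
                         test.df[output].to_numpy(dtype=float))
    return mlp_train(X, y, cfg)


def select_best_snapshot(trace: TrainingTrace,
                         criterion: str = "test_rmse") -> MLPModel:
    """Pick the snapshot minimizing train or held-out RMSE (ties: earliest).

    Selecting on held-out RMSE mirrors the study's stop-point model choice;
    note the held-out set then participates in model selection, so the
    reported generalization error is mildly optimistic.
    """
    if not trace.snapshots:
        raise ValueError("empty training trace")
    if criterion not in ("test_rmse", "train_rmse"):
        raise ValueError(f"unknown criterion {criterion!r}")
    vals = [getattr(s, criterion) for s in trace.snapshots]
    if any(v is None for v in vals):
        raise ValueError(f"{criterion} not recorded in the trace")
    best = min(range(len(vals)), key=lambda k: (vals[k], trace.snapshots[k].epoch))
    snap = trace.snapshots[best]
    if trace.config is None:
        raise ValueError("trace carries no MLPConfig")
    return MLPModel([(W.copy(), b.copy()) for W, b in snap.weights],
                    config=trace.config,
                    epochs_trained=snap.epoch)
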