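"""Single-hidden-layer sigmoid perceptron trained by online backpropagation.

The network is the classical three-layer design: a propagation function
S_i = sum_n w_ni x_n + b_i feeding a sigmoid activation y_i = 1/(1+e^-S_i),
applied uniformly to the intermediate and output layers, with the
half-sum-of-squares error E = 1/2 sum (d_o - y_o)^2.  Topologies are
written "input-intermediate-output", e.g. "10-18-1".

Training is per-example gradient descent with momentum for an exact number
of cycles (one cycle = one seeded-shuffled pass over the training rows);
overfitting is controlled by the choice of cycle count, not by early
stopping.  :func:`train_until_plateau` offers an APS-plateau stop for
budgeted sweeps.

Categorical outputs use one neuron per target variable with equally
spaced codes (see :mod:`glmaid.preprocessing`), so a three-variable
authenticator has 3 output neurons and a single-variable one has 1.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .preprocessing import decode_target, encode_target


@dataclass(frozen=True)
class Topology:
    n_input: int
    n_intermediate: int
    n_output: int

    def __post_init__(self):
        for v in (self.n_input, self.n_intermediate, self.n_output):
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"layer sizes must be positive integers, "
                                 f"got {self}")

    def __str__(self) -> str:
        return f"{self.n_input}-{self.n_intermediate}-{self.n_output}"


def parse_topology(text: str) -> Topology:
    """Parse "a-b-c" into a Topology (three positive integers)."""
    m = re.fullmatch(r"\s*(\d+)-(\d+)-(\d+)\s*", str(text))
    if not m:
        raise ValueError(f"malformed topology {text!r}; expected 'a-b-c'")
    return Topology(*(int(g) for g in m.groups()))


@dataclass
class Network:
    """Layered weights and biases: w1 (input->hidden), b1, w2
    (hidden->output), b2."""

    topology: Topology
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    seed: int = 0

    def copy(self) -> "Network":
        return Network(self.topology, self.w1.copy(), self.b1.copy(),
                       self.w2.copy(), self.b2.copy(), self.seed)

    @property
    def n_free_parameters(self) -> int:
        return (self.w1.size + self.b1.size + self.w2.size + self.b2.size)


@dataclass
class TrainingConfig:
    cycles: int
    learning_rate: float = 0.6
    momentum: float = 0.8
    seed: int = 0
    shuffle_each_cycle: bool = True

    def __post_init__(self):
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


def init_network(topology: Topology, seed: int = 0) -> Network:
    """Weights and biases drawn uniformly from [-0.5, 0.5], seeded."""
    rng = np.random.default_rng(seed)
    return Network(
        topology=topology,
        w1=rng.uniform(-0.5, 0.5, (topology.n_input, topology.n_intermediate)),
        b1=rng.uniform(-0.5, 0.5, topology.n_intermediate),
        w2=rng.uniform(-0.5, 0.5, (topology.n_intermediate, topology.n_output)),
        b2=rng.uniform(-0.5, 0.5, topology.n_output),
        seed=seed)


def _sigmoid(s: np.ndarray) -> np.ndarray:
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out


def forward(net: Network, x) -> tuple[np.ndarray, np.ndarray]:
    """Propagate inputs; returns (hidden activations, outputs).

    Accepts a single input vector or a (n, n_input) matrix; the same
    propagation/activation pair is applied at both layers.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != net.topology.n_input:
        raise ValueError(f"input length {X.shape[1]} != n_input "
                         f"{net.topology.n_input}")
    H = _sigmoid(X @ net.w1 + net.b1)
    Y = _sigmoid(H @ net.w2 + net.b2)
    return (H[0], Y[0]) if single else (H, Y)


def sse_error(desired, predicted) -> float:
    """Half the sum of squared differences, E = 1/2 sum (d - y)^2."""
    d = np.asarray(desired, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if d.shape != y.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {y.shape}")
    return 0.5 * float(np.sum((d - y) ** 2))


def batch_gradient(net: Network, X, D) -> tuple[np.ndarray, ...]:
    """Analytic gradient of the total error over a batch.

    Returns (dE/dw1, dE/db1, dE/dw2, dE/db2) for
    E = sum_examples 1/2 sum_outputs (d - y)^2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    H, Y = forward(net, X)
    delta_out = (Y - D) * Y * (1.0 - Y)
    delta_hid = (delta_out @ net.w2.T) * H * (1.0 - H)
    return (X.T @ delta_hid, delta_hid.sum(axis=0),
            H.T @ delta_out, delta_out.sum(axis=0))


def train(net: Network, inputs, targets, config: TrainingConfig
          ) -> tuple[Network, np.ndarray]:
    """Online backpropagation for exactly ``config.cycles`` cycles.

    Returns a trained copy of the network and the per-cycle error trace
    (total E accumulated over the examples of each pass, evaluated at the
    pre-update state of each example).  Fully deterministic given
    (net, data, config).
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    D = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] != D.shape[0]:
        raise ValueError("inputs and targets row counts differ")
    if D.min() < 0 or D.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    net = net.copy()
    lr, mom = config.learning_rate, config.momentum
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    dw1 = np.zeros_like(net.w1)
    db1 = np.zeros_like(net.b1)
    dw2 = np.zeros_like(net.w2)
    db2 = np.zeros_like(net.b2)
    trace = np.empty(config.cycles)
    order = np.arange(n)
    for cycle in range(config.cycles):
        if config.shuffle_each_cycle:
            order = rng.permutation(n)
        total = 0.0
        for i in order:
            x, d = X[i], D[i]
            h = _sigmoid(x @ net.w1 + net.b1)
            y = _sigmoid(h @ net.w2 + net.b2)
            err = d - y
            total += 0.5 * float(err @ err)
            delta_out = -err * y * (1.0 - y)
            delta_hid = (net.w2 @ delta_out) * h * (1.0 - h)
            dw2 = -lr * np.outer(h, delta_out) + mom * dw2
            db2 = -lr * delta_out + mom * db2
            dw1 = -lr * np.outer(x, delta_hid) + mom * dw1
            db1 = -lr * delta_hid + mom * db1
            net.w2 += dw2
            net.b2 += db2
            net.w1 += dw1
            net.b1 += db1
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite training error at cycle {cycle}")
        trace[cycle] = total
    return net, trace


def predict(net: Network, inputs, output_codebooks: list) -> np.ndarray:
    """Decode each output neuron to the nearest equally spaced code.

    ``output_codebooks`` holds one ordered level list per output neuron.
    Returns an object array of shape (n_samples, n_output).
    """
    if len(output_codebooks) != net.topology.n_output:
        raise ValueError("one codebook per output neuron required")
    _, Y = forward(net, np.atleast_2d(np.asarray(inputs, dtype=float)))
    cols = [decode_target(Y[:, k], levels)
            for k, levels in enumerate(output_codebooks)]
    return np.stack(cols, axis=1)


def _plateaued(history: list[float], patience: int, rel: float) -> bool:
    """True when the best error of the last ``patience`` checks improved on
    the best before them by less than ``rel`` (relative)."""
    if len(history) <= patience:
        return False
    old = min(history[:-patience])
    recent = min(history[-patience:])
    return recent >= old - max(rel * old, 1e-12)


def train_until_plateau(net: Network, inputs, targets,
                        config: TrainingConfig,
                        max_cycles: int | None = None,
                        check_every: int = 250, patience: int = 8,
                        rel_improvement: float = 0.01
                        ) -> tuple[Network, int]:
    """Train in chunks, stopping when training error stops improving.

    Runs ``check_every``-cycle chunks up to ``max_cycles`` (default
    ``config.cycles``) and stops once the best chunk-final error of the
    last ``patience`` chunks is no longer ``rel_improvement`` better than
    the best before them.  Returns the trained network and the number of
    cycles actually run.
    """
    max_cycles = config.cycles if max_cycles is None else max_cycles
    history: list[float] = []
    run = 0
    chunk_idx = 0
    while run < max_cycles:
        cycles = min(check_every, max_cycles - run)
        chunk_cfg = replace(config, cycles=cycles,
                            seed=(config.seed + 0x9E37 * chunk_idx) % (2**31))
        net, trace = train(net, inputs, targets, chunk_cfg)
        run += cycles
        chunk_idx += 1
        history.append(float(trace[-1]))
        if _plateaued(history, patience, rel_improvement):
            break
    return net, run


def train_ensemble(nets: list[Network], inputs, targets,
                   config: TrainingConfig) -> list[Network]:
    """Train several equally shaped networks in lockstep.

    All networks see the same seeded example order each cycle (they differ
    in their initializations), which lets the per-example update run
    vectorized across the ensemble.  Semantically each network receives
    exactly the online backpropagation of :func:`train`.
    """
    topo = nets[0].topology
    if any(n.topology != topo for n in nets):
        raise ValueError("ensemble networks must share one topology")
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    D = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] != D.shape[0]:
        raise ValueError("inputs and targets row counts differ")
    if D.min() < 0 or D.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    K = len(nets)
    W1 = np.stack([n.w1 for n in nets])
    B1 = np.stack([n.b1 for n in nets])
    W2 = np.stack([n.w2 for n in nets])
    B2 = np.stack([n.b2 for n in nets])
    dW1 = np.zeros_like(W1)
    dB1 = np.zeros_like(B1)
    dW2 = np.zeros_like(W2)
    dB2 = np.zeros_like(B2)
    lr, mom = config.learning_rate, config.momentum
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    order = np.arange(n)
    for _ in range(config.cycles):
        if config.shuffle_each_cycle:
            order = rng.permutation(n)
        for i in order:
            x, d = X[i], D[i]
            H = _sigmoid(np.einsum("kih,i->kh", W1, x) + B1)
            Y = _sigmoid(np.einsum("kho,kh->ko", W2, H) + B2)
            delta_out = (Y - d) * Y * (1.0 - Y)
            delta_hid = np.einsum("kho,ko->kh", W2, delta_out) * H * (1.0 - H)
            dW2 = -lr * H[:, :, None] * delta_out[:, None, :] + mom * dW2
            dB2 = -lr * delta_out + mom * dB2
            dW1 = -lr * x[None, :, None] * delta_hid[:, None, :] + mom * dW1
            dB1 = -lr * delta_hid + mom * dB1
            W2 += dW2
            B2 += dB2
            W1 += dW1
            B1 += dB1
    return [Network(topo, W1[k].copy(), B1[k].copy(), W2[k].copy(),
                    B2[k].copy(), nets[k].seed) for k in range(K)]


# ---------------------------------------------------------------------------
# serialization

NETWORK_SCHEMA = "glmaid-network/1"


def network_to_dict(net: Network, **metadata) -> dict:
    return {
        "schema": NETWORK_SCHEMA,
        "topology": str(net.topology),
        "seed": int(net.seed),
        "w1": net.w1.tolist(), "b1": net.b1.tolist(),
        "w2": net.w2.tolist(), "b2": net.b2.tolist(),
        "metadata": metadata,
    }


def network_from_dict(d: dict) -> tuple[Network, dict]:
    if d.get("schema") != NETWORK_SCHEMA:
        raise ValueError(f"unsupported network schema: {d.get('schema')!r}")
    topo = parse_topology(d["topology"])
    net = Network(topology=topo,
                  w1=np.asarray(d["w1"], dtype=float),
                  b1=np.asarray(d["b1"], dtype=float),
                  w2=np.asarray(d["w2"], dtype=float),
                  b2=np.asarray(d["b2"], dtype=float),
                  seed=int(d.get("seed", 0)))
    if net.w1.shape != (topo.n_input, topo.n_intermediate) or \
            net.w2.shape != (topo.n_intermediate, topo.n_output):
        raise ValueError("weight shapes do not match topology")
    return net, d.get("metadata", {})


def save_network(net: Network, path, **metadata) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net, **metadata), fh)


def load_network(path) -> tuple[Network, dict]:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# estimator interface

class SigmoidMLP(BaseEstimator):
    """Scikit-learn-style front end to the sigmoid perceptron.

    ``fit(X, y)`` accepts labels as a 1-d vector (single output) or a
    2-d array / DataFrame with one column per target variable; each
    variable occupies one output neuron with equally spaced codes.

    Parameters mirror :class:`TrainingConfig` plus the hidden-layer width;
    ``output_levels`` optionally fixes the level order per output (else
    sorted unique labels are used).
    """

    def __init__(self, hidden: int = 18, cycles: int = 1000,
                 learning_rate: float = 0.6, momentum: float = 0.8,
                 seed: int = 0, shuffle_each_cycle: bool = True,
                 output_levels: list | None = None):
        self.hidden = hidden
        self.cycles = cycles
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.seed = seed
        self.shuffle_each_cycle = shuffle_each_cycle
        self.output_levels = output_levels

    def _as_label_matrix(self, y) -> np.ndarray:
        arr = np.asarray(y, dtype=object)
        return arr.reshape(-1, 1) if arr.ndim == 1 else arr

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = self._as_label_matrix(y)
        if self.output_levels is not None:
            self.output_levels_ = [tuple(l) for l in self.output_levels]
        else:
            self.output_levels_ = [
                tuple(sorted(set(Y[:, k]))) for k in range(Y.shape[1])]
        D = np.column_stack([
            encode_target(Y[:, k], self.output_levels_[k])
            for k in range(Y.shape[1])])
        topo = Topology(X.shape[1], self.hidden, Y.shape[1])
        cfg = TrainingConfig(cycles=self.cycles,
                             learning_rate=self.learning_rate,
                             momentum=self.momentum, seed=self.seed,
                             shuffle_each_cycle=self.shuffle_each_cycle)
        net = init_network(topo, seed=self.seed)
        self.network_, self.error_trace_ = train(net, X, D, cfg)
        return self

    def predict(self, X):
        out = predict(self.network_, X, self.output_levels_)
        return out[:, 0] if len(self.output_levels_) == 1 else out

    def score(self, X, y):
        """Mean per-output fraction of exact label matches."""
        pred = self._as_label_matrix(self.predict(X))
        truth = self._as_label_matrix(y)
        return float(np.mean(pred == truth))
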