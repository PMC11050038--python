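"""Stage II: feed-forward network trained by back-propagation of errors (BPE).

One hidden layer of logistic-sigmoid units and a single output unit, trained
online (per pattern) by the delta rule with a momentum term.  In the combined
two-stage method this network is trained not on compounds but on the neurons
extracted from a trained CP-ANN - the Kohonen weight vectors as inputs and
the Grossberg values as targets - which is enforced here by accepting a
:class:`~cpbpe.cpann.NeuronDataset` as the training container.  Because the
output unit is a sigmoid, predictions are continuous and interpolate between
the minimal and maximal training target values: distinct inputs mapping to
the same CP-ANN neuron generically receive distinct outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import train_bpe_online
from .cpann import NeuronDataset
from .data import ConfigurationError

# epochs per compiled-kernel call; bounds the presentation-schedule memory
_EPOCH_BLOCK = 4000


@dataclass
class BPEConfig:
    """Back-propagation training settings.

    Defaults follow the standard QSAR practice for this family of models:
    learning rate 0.1, momentum 0.01, 1000 epochs.  ``init_range`` bounds the
    uniform weight initialisation; ``output_activation`` may be "linear" for
    ablation against the default sigmoid output unit.
    """

    hidden_neurons: int
    learning_rate: float = 0.1
    momentum: float = 0.01
    epochs: int = 1000
    seed: int = 0
    init_range: float = 0.5
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ConfigurationError("hidden_neurons must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.momentum < 0:
            raise ConfigurationError("momentum must be >= 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.init_range <= 0:
            raise ConfigurationError("init_range must be > 0")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ConfigurationError("output_activation must be sigmoid or linear")


@dataclass
class BPENetwork:
    """Layered weights with momentum state.  ``w_hidden`` is (n+1) x hidden
    with the bias as the final row (bias handled as a constant-1 input);
    ``w_out`` is (hidden+1,) with the bias last."""

    w_hidden: np.ndarray
    w_out: np.ndarray
    prev_dw_hidden: np.ndarray
    prev_dw_out: np.ndarray
    config: BPEConfig
    rmse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        h = self.config.hidden_neurons
        if self.w_hidden.shape[1] != h or self.w_out.shape != (h + 1,):
            raise ConfigurationError("weight shapes inconsistent with hidden_neurons")
        if self.prev_dw_hidden.shape != self.w_hidden.shape \
                or self.prev_dw_out.shape != self.w_out.shape:
            raise ConfigurationError("momentum state shapes inconsistent")
        if not (np.isfinite(self.w_hidden).all() and np.isfinite(self.w_out).all()):
            raise ConfigurationError("non-finite weights")

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[0] - 1


def _sigmoid(z: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-z))


def new_network(n_inputs: int, config: BPEConfig) -> BPENetwork:
    """Fresh network with weights uniform in [-init_range, +init_range]."""
    rng = np.random.default_rng(config.seed)
    h = config.hidden_neurons
    return BPENetwork(
        w_hidden=rng.uniform(-config.init_range, config.init_range, (n_inputs + 1, h)),
        w_out=rng.uniform(-config.init_range, config.init_range, h + 1),
        prev_dw_hidden=np.zeros((n_inputs + 1, h)),
        prev_dw_out=np.zeros(h + 1),
        config=config)


def forward(net: BPENetwork, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Forward pass: (output, hidden activations).

    hidden_j = sigma(sum_i w_ij x_i + b_j); output = sigma(sum_j v_j hidden_j + c)
    with sigma(z) = 1/(1+exp(-z)) (output linear in ablation mode).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ConfigurationError(
            f"input length {x.size} does not match network inputs {net.n_inputs}")
    hidden = _sigmoid(net.w_hidden[:-1].T @ x + net.w_hidden[-1])
    z = float(net.w_out[:-1] @ hidden + net.w_out[-1])
    out = _sigmoid(z) if net.config.output_activation == "sigmoid" else z
    return out, hidden


def gradients(net: BPENetwork, x: np.ndarray, target: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of E = 1/2 (output - target)^2 w.r.t. both layers."""
    out, hidden = forward(net, x)
    delta_o = (out - target) * (out * (1.0 - out)
                                if net.config.output_activation == "sigmoid" else 1.0)
    g_out = np.append(delta_o * hidden, delta_o)
    delta_h = delta_o * net.w_out[:-1] * hidden * (1.0 - hidden)
    x = np.asarray(x, dtype=float)
    g_hidden = np.vstack([np.outer(x, delta_h), delta_h])
    return g_hidden, g_out


def backprop_step(net: BPENetwork, x: np.ndarray, target: float) -> BPENetwork:
    """One online delta-rule update with momentum, in place:
    dw(t) = -eta * dE/dw + mu * dw(t-1).  Returns the network."""
    if not np.isfinite(target):
        raise ConfigurationError("target must be finite")
    g_hidden, g_out = gradients(net, x, target)
    eta, mu = net.config.learning_rate, net.config.momentum
    d_hidden = -eta * g_hidden + mu * net.prev_dw_hidden
    d_out = -eta * g_out + mu * net.prev_dw_out
    net.w_hidden += d_hidden
    net.w_out += d_out
    net.prev_dw_hidden = d_hidden
    net.prev_dw_out = d_out
    return net


def train_bpe(neurons: NeuronDataset, config: BPEConfig) -> BPENetwork:
    """Train a network on the extracted CP-ANN neurons.

    Weights start uniform in [-init_range, +init_range] from the seed; each
    epoch presents the neurons in a freshly shuffled order and applies
    :func:`backprop_step` per pattern (the compiled kernel runs the identical
    update).  The returned network carries the per-epoch training RMSE trace
    (scaled units, running outputs of each pass).
    """
    if neurons.k < 1:
        raise ConfigurationError("neuron dataset is empty")
    targets = np.asarray(neurons.targets, dtype=float)
    if targets.min() < 0.0 or targets.max() > 1.0:
        raise ConfigurationError("neuron targets must lie in [0, 1] (scaled)")
    rng = np.random.default_rng(config.seed)
    h = config.hidden_neurons
    net = BPENetwork(
        w_hidden=rng.uniform(-config.init_range, config.init_range, (neurons.n + 1, h)),
        w_out=rng.uniform(-config.init_range, config.init_range, h + 1),
        prev_dw_hidden=np.zeros((neurons.n + 1, h)),
        prev_dw_out=np.zeros(h + 1),
        config=config)
    inputs = np.ascontiguousarray(neurons.inputs, dtype=float)
    # epochs are run in blocks so the presentation schedule never occupies
    # more than a few MB; the kernel updates all state in place, so blocked
    # calls are identical to one long call
    traces = []
    for start in range(0, config.epochs, _EPOCH_BLOCK):
        n_epochs = min(_EPOCH_BLOCK, config.epochs - start)
        orders = np.argsort(rng.random((n_epochs, neurons.k)), axis=1).astype(np.int64)
        traces.append(train_bpe_online(
            inputs, targets, net.w_hidden, net.w_out,
            net.prev_dw_hidden, net.prev_dw_out, orders,
            config.learning_rate, config.momentum,
            config.output_activation == "sigmoid"))
    trace = np.concatenate(traces)
    if not np.isfinite(trace).all():
        raise ArithmeticError(
            "training diverged (non-finite loss); try a lower learning_rate")
    net.rmse_trace = trace
    return net


def predict_bpe(net: BPENetwork, x: np.ndarray) -> float:
    """Forward pass, output component only (scaled units)."""
    return forward(net, x)[0]


def predict_bpe_batch(net: BPENetwork, X: np.ndarray) -> np.ndarray:
    """Vectorised forward pass over rows of a scaled matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise ConfigurationError(
            f"input width {X.shape[1]} does not match network inputs {net.n_inputs}")
    hidden = _sigmoid(X @ net.w_hidden[:-1] + net.w_hidden[-1])
    z = hidden @ net.w_out[:-1] + net.w_out[-1]
    return _sigmoid(z) if net.config.output_activation == "sigmoid" else z
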