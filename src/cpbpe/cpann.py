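"""Stage I: counter-propagation artificial neural network (CP-ANN).

A CP-ANN couples an unsupervised competitive Kohonen layer - a 2-D grid of
weight vectors living in scaled descriptor space - with a supervised Grossberg
output layer holding one response value per grid neuron.  Training presents
compounds one at a time: the neuron closest to the compound wins, and every
neuron is corrected toward the compound's descriptors (Kohonen layer) and its
target (Grossberg layer) with a strength that decays with grid distance from
the winner and with epoch number.  Prediction is a lookup: the winning
neuron's Grossberg value.  That lookup can emit at most one value per neuron,
which is the limitation the second (back-propagation) stage removes; this
module also extracts the trained neurons as that stage's surrogate training
set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import (ConfigurationError, Dataset, ScalingParams, fit_scaling,
                   inverse_scale_target, scale_matrix, scale_vector)

TOPOLOGIES = ("planar", "toroidal")
NEIGHBORHOODS = ("triangular", "rectangular")


@dataclass
class CPANNConfig:
    """Kohonen/Grossberg training settings.

    The learning rate decays linearly from ``eta_max`` to ``eta_min`` and the
    neighbourhood radius from ``max(map_rows, map_cols)/2`` to 0 over the
    epochs; updates are per-pattern (online) in a seed-shuffled order.
    """

    map_rows: int
    map_cols: int
    epochs: int = 200
    eta_max: float = 0.5
    eta_min: float = 0.01
    topology: str = "planar"
    neighborhood: str = "triangular"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map_rows < 1 or self.map_cols < 1:
            raise ConfigurationError("map dimensions must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not (self.eta_max >= self.eta_min > 0):
            raise ConfigurationError("need eta_max >= eta_min > 0")
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(f"topology must be one of {TOPOLOGIES}")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ConfigurationError(f"neighborhood must be one of {NEIGHBORHOODS}")

    @property
    def k(self) -> int:
        """Number of neurons in the grid."""
        return self.map_rows * self.map_cols


@dataclass
class CPANNModel:
    """Trained CP-ANN: Kohonen weight grid W (rows x cols x n, scaled
    descriptor space), Grossberg grid (rows x cols, scaled target space), the
    scaling used, and the training-distance record feeding the
    applicability-domain threshold."""

    kohonen: np.ndarray
    grossberg: np.ndarray
    config: CPANNConfig
    scaling: ScalingParams
    train_distances: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        r, c = self.config.map_rows, self.config.map_cols
        if self.kohonen.shape[:2] != (r, c) or self.grossberg.shape != (r, c):
            raise ConfigurationError("weight grids do not match the configured map size")
        if not np.isfinite(self.grossberg).all():
            raise ConfigurationError("non-finite Grossberg values")

    @property
    def n(self) -> int:
        return self.kohonen.shape[2]


@dataclass
class NeuronDataset:
    """The k (Kohonen weight vector, Grossberg value) pairs of a trained
    CP-ANN, used as the Stage II training objects (both in scaled space)."""

    inputs: np.ndarray
    targets: np.ndarray
    neuron_coords: list[tuple[int, int]]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.inputs.shape[0] != self.targets.size != len(self.neuron_coords):
            raise ConfigurationError("inconsistent neuron dataset shapes")

    @property
    def k(self) -> int:
        return self.inputs.shape[0]

    @property
    def n(self) -> int:
        return self.inputs.shape[1]


# ---------------------------------------------------------------------------
# Winner search and neighbourhood
# ---------------------------------------------------------------------------

def find_winner(kohonen: np.ndarray, x: np.ndarray) -> tuple[int, int, float]:
    """Neuron minimising Euclidean distance to ``x``; ties break to the
    smallest row-major index."""
    x = np.asarray(x, dtype=float)
    rows, cols, n = kohonen.shape
    if x.shape != (n,):
        raise ConfigurationError(f"input length {x.size} does not match n={n}")
    d2 = ((kohonen - x) ** 2).sum(axis=2)
    flat = int(np.argmin(d2))  # argmin returns the first minimum in row-major order
    return flat // cols, flat % cols, float(np.sqrt(d2.flat[flat]))


def batch_winners(kohonen: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winning flat neuron index and distance for every row of ``X``."""
    rows, cols, n = kohonen.shape
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != n:
        raise ConfigurationError(f"input width {X.shape[1]} does not match n={n}")
    d = cdist(X, kohonen.reshape(rows * cols, n))
    winners = d.argmin(axis=1)
    return winners, d[np.arange(len(X)), winners]


def _grid_distance(winner: tuple[int, int], rows: int, cols: int,
                   topology: str) -> np.ndarray:
    """Chebyshev (topological) distance of every neuron to the winner, with
    wrap-around on a toroidal map."""
    wr, wc = winner
    dr = np.abs(np.arange(rows) - wr)
    dc = np.abs(np.arange(cols) - wc)
    if topology == "toroidal":
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    return np.maximum(dr[:, None], dc[None, :])


def neighborhood_grid(winner: tuple[int, int], rows: int, cols: int,
                      radius: float, topology: str = "planar",
                      shape: str = "triangular") -> np.ndarray:
    """Correction factor a(neuron) in [0, 1] for the whole grid."""
    if radius < 0:
        raise ConfigurationError("radius must be >= 0")
    d = _grid_distance(winner, rows, cols, topology)
    if shape == "rectangular":
        return (d <= radius).astype(float)
    return np.maximum(0.0, 1.0 - d / (radius + 1.0))


def neighborhood_factor(winner: tuple[int, int], neuron: tuple[int, int],
                        radius: float, rows: int, cols: int,
                        topology: str = "planar",
                        shape: str = "triangular") -> float:
    """Scalar neighbourhood factor for one neuron.

    Triangular: max(0, 1 - d/(radius+1)); rectangular: 1 if d <= radius else 0,
    where d is the Chebyshev grid distance (wrap-around if toroidal).  At
    radius 0 only the winner is corrected (triangular shape)."""
    grid = neighborhood_grid(winner, rows, cols, radius, topology, shape)
    return float(grid[neuron[0], neuron[1]])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def update_step(kohonen: np.ndarray, grossberg: np.ndarray | None,
                x: np.ndarray, t: float | None, eta: float, radius: float,
                topology: str = "planar", shape: str = "triangular"
                ) -> tuple[int, int]:
    """One online correction: find the winner of ``x`` and move every neuron's
    Kohonen weights toward ``x`` and (if supervised) its Grossberg value
    toward ``t`` by eta * a(neuron) * (component - weight).  Mutates the grids
    in place; returns the winner coordinates."""
    rows, cols, _ = kohonen.shape
    wr, wc, _dist = find_winner(kohonen, x)
    a = neighborhood_grid((wr, wc), rows, cols, radius, topology, shape)
    kohonen += (eta * a)[:, :, None] * (x - kohonen)
    if grossberg is not None:
        if t is None:
            raise ConfigurationError("supervised update requires a target")
        grossberg += eta * a * (t - grossberg)
    return wr, wc


def _schedule(config: CPANNConfig, epoch: int) -> tuple[float, float]:
    frac = epoch / (config.epochs - 1) if config.epochs > 1 else 1.0
    eta = config.eta_max + frac * (config.eta_min - config.eta_max)
    radius = (max(config.map_rows, config.map_cols) / 2.0) * (1.0 - frac)
    return eta, radius


def _train_grids(Xs: np.ndarray, Ts: np.ndarray | None, config: CPANNConfig
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    m, n = Xs.shape
    rng = np.random.default_rng(config.seed)
    kohonen = rng.uniform(0.0, 1.0, size=(config.map_rows, config.map_cols, n))
    grossberg = rng.uniform(0.0, 1.0, size=(config.map_rows, config.map_cols)) \
        if Ts is not None else None
    for epoch in range(config.epochs):
        eta, radius = _schedule(config, epoch)
        for s in rng.permutation(m):
            update_step(kohonen, grossberg, Xs[s],
                        None if Ts is None else float(Ts[s]),
                        eta, radius, config.topology, config.neighborhood)
    return kohonen, grossberg


def train_kohonen(Xs: np.ndarray, config: CPANNConfig) -> np.ndarray:
    """Unsupervised Kohonen map on pre-scaled data (no Grossberg layer); used
    by the SOM splitter and the descriptor-grouping reduction."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    if Xs.size == 0:
        raise ConfigurationError("empty training matrix")
    weights, _ = _train_grids(Xs, None, config)
    return weights


def train_cpann(train: Dataset, config: CPANNConfig,
                scaling: ScalingParams | None = None) -> CPANNModel:
    """Train the CP-ANN on a scaled training Dataset.

    ``train`` must already be in scaled space (descriptors ~[0,1], target in
    [target_low, target_high]); ``scaling`` records the transformation so the
    model can accept raw descriptor vectors at prediction time.  Weights are
    initialised uniformly in [0,1] from the seed; compounds are presented in a
    freshly shuffled order each epoch; Kohonen and Grossberg layers receive
    the same eta * a correction in the same pass.  After training, each
    training compound's distance to its winning neuron and the per-neuron
    occupancy are recorded with the final weights.
    """
    if train.m < 1 or train.n < 1:
        raise ConfigurationError("training set must be nonempty")
    if scaling is None:
        scaling = fit_scaling(train)
    kohonen, grossberg = _train_grids(train.X, train.T, config)
    winners, distances = batch_winners(kohonen, train.X)
    occupancy = np.bincount(winners, minlength=config.k).reshape(
        config.map_rows, config.map_cols)
    return CPANNModel(kohonen=kohonen, grossberg=grossberg, config=config,
                      scaling=scaling, train_distances=distances,
                      occupancy=occupancy)


# ---------------------------------------------------------------------------
# Prediction and neuron extraction
# ---------------------------------------------------------------------------

def predict_cpann(model: CPANNModel, x: np.ndarray
                  ) -> tuple[float, tuple[int, int], float]:
    """Stage I lookup for one raw descriptor vector: scale, find the winner,
    return its Grossberg value in original target units.  Every compound
    exciting the same neuron receives the same value."""
    xs = scale_vector(x, model.scaling)
    row, col, dist = find_winner(model.kohonen, xs)
    value = inverse_scale_target(float(model.grossberg[row, col]), model.scaling)
    return value, (row, col), dist


def predict_cpann_batch(model: CPANNModel, X: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Stage I lookup: (values in target units, flat winner
    indices, distances) for each row of raw descriptors."""
    Xs = scale_matrix(X, model.scaling)
    winners, distances = batch_winners(model.kohonen, Xs)
    values = inverse_scale_target(model.grossberg.ravel()[winners], model.scaling)
    return values, winners, distances


def extract_neurons(model: CPANNModel, occupied_only: bool = False) -> NeuronDataset:
    """Extract the trained neurons as the Stage II training set.

    By default all k neurons are returned, occupied or empty: neighbourhood
    training leaves empty neurons with smoothed Grossberg values, so they are
    representative objects in their own right.  ``occupied_only=True`` keeps
    only neurons that some training compound excites (ablation mode).
    """
    rows, cols, n = model.kohonen.shape
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    inputs = model.kohonen.reshape(rows * cols, n).copy()
    targets = model.grossberg.ravel().copy()
    occupancy = model.occupancy.ravel().copy()
    if occupied_only:
        keep = occupancy > 0
        inputs, targets, occupancy = inputs[keep], targets[keep], occupancy[keep]
        coords = [coords[i] for i in np.nonzero(keep)[0]]
    return NeuronDataset(inputs=inputs, targets=targets, neuron_coords=coords,
                         occupancy=occupancy)


# ---------------------------------------------------------------------------
# Descriptor reduction
# ---------------------------------------------------------------------------

def reduce_descriptors(dataset: Dataset, corr_threshold: float = 0.95,
                       var_threshold: float = 0.005, map_rows: int = 3,
                       map_cols: int = 3, seed: int = 0,
                       epochs: int = 100) -> list[str]:
    """Three-step descriptor reduction on min-max scaled values.

    1. Drop descriptors whose scaled variance is below ``var_threshold``.
    2. For each pair with |Pearson r| above ``corr_threshold``, drop the
       later column in file order.
    3. Group the survivors with a Kohonen map trained on the transposed
       scaled matrix (descriptors as objects, compounds as features); from
       each occupied neuron keep the descriptor closest to and the descriptor
       farthest from that neuron's weight vector (just one if singly
       occupied), and return the union, in file order.
    """
    if dataset.n < 2:
        raise ConfigurationError("descriptor reduction needs at least 2 descriptors")
    params = fit_scaling(dataset)
    Xs = scale_matrix(dataset.X, params)
    names = list(dataset.descriptor_names)

    keep = [i for i in range(len(names)) if np.var(Xs[:, i], ddof=1) >= var_threshold]
    if not keep:
        raise ConfigurationError("variance filter removed every descriptor")

    surv: list[int] = []
    for i in keep:
        correlated = False
        for j in surv:
            r = np.corrcoef(Xs[:, j], Xs[:, i])[0, 1]
            if np.isfinite(r) and abs(r) > corr_threshold:
                correlated = True
                break
        if not correlated:
            surv.append(i)
    if not surv:
        raise ConfigurationError("correlation filter removed every descriptor")

    # descriptors as objects on the transposed matrix
    objects = Xs[:, surv].T
    config = CPANNConfig(map_rows=map_rows, map_cols=map_cols, epochs=epochs,
                         seed=seed)
    weights = train_kohonen(objects, config)
    winners, distances = batch_winners(weights, objects)
    selected: set[int] = set()
    for j in np.unique(winners):
        occ = np.nonzero(winners == j)[0]
        selected.add(surv[occ[np.argmin(distances[occ])]])
        selected.add(surv[occ[np.argmax(distances[occ])]])
    return [names[i] for i in sorted(selected)]
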