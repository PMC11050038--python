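"""Synthetic descriptor/property tables for offline testing and examples.

Real QSAR descriptor tables are external; this module generates tables with
the same shape and the statistical features the modelling pipeline cares
about: an m x n descriptor matrix (optionally clustered, with pure-nuisance
columns) whose target is a smooth function of the informative descriptors
plus Gaussian noise, emitted in a logS-like range so reports read like
solubility modelling.  Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ConfigurationError, Dataset

FUNCTIONS = ("linear", "quadratic", "sinusoidal", "clustered-plateau")

# realized smooth-function values are mapped affinely onto this window,
# a typical span for curated log-property datasets
TARGET_WINDOW = (-7.0, -2.0)
CLUSTER_JITTER = 0.15


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    The first ``n_informative`` descriptors drive the target through the
    chosen smooth function; the remaining columns are pure nuisance.
    ``noise_sd`` is the Gaussian noise standard deviation in target units.
    """

    m: int
    n: int
    n_informative: int | None = None
    function: str = "quadratic"
    noise_sd: float = 0.1
    cluster_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative is None:
            self.n_informative = self.n
        if self.m < 1 or self.n < 1:
            raise ConfigurationError("m and n must be positive")
        if not (1 <= self.n_informative <= self.n):
            raise ConfigurationError("need 1 <= n_informative <= n")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.cluster_count < 1:
            raise ConfigurationError("cluster_count must be >= 1")


def _smooth_function(Z: np.ndarray, function: str, assignment: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    p = Z.shape[1]
    if function == "linear":
        coef = rng.uniform(0.5, 2.0, p) * rng.choice([-1.0, 1.0], p)
        return Z @ coef
    if function == "quadratic":
        coef = rng.uniform(0.5, 2.0, p) * rng.choice([-1.0, 1.0], p)
        quad = rng.uniform(-0.8, 0.8, (p, p))
        quad = (quad + quad.T) / 2.0
        return Z @ coef + np.einsum("si,ij,sj->s", Z, quad, Z)
    if function == "sinusoidal":
        coef = rng.uniform(0.5, 1.5, p)
        phase = rng.uniform(0.0, 2.0 * np.pi, p)
        return np.sin(np.pi * Z + phase) @ coef
    # clustered-plateau: target depends on the cluster only
    levels = rng.permutation(np.linspace(0.0, 1.0, int(assignment.max()) + 1))
    return levels[assignment]


def generate(spec: SyntheticSpec) -> Dataset:
    """Build a Dataset from a :class:`SyntheticSpec`.

    Descriptors are uniform on [0,1] (``cluster_count=1``) or drawn as
    cluster centre + uniform jitter; the raw smooth-function values are
    mapped onto the logS-like window before adding noise, so ``noise_sd``
    is in target units.  With ``noise_sd=0`` and ``n_informative=n`` the
    target is an exact function of the descriptors.
    """
    if spec.function not in FUNCTIONS:
        raise ConfigurationError(f"function must be one of {FUNCTIONS}")
    rng = np.random.default_rng(spec.seed)
    if spec.cluster_count == 1:
        X = rng.uniform(0.0, 1.0, (spec.m, spec.n))
        assignment = np.zeros(spec.m, dtype=int)
    else:
        centers = rng.uniform(CLUSTER_JITTER, 1.0 - CLUSTER_JITTER,
                              (spec.cluster_count, spec.n))
        assignment = rng.integers(spec.cluster_count, size=spec.m)
        X = centers[assignment] + rng.uniform(-CLUSTER_JITTER, CLUSTER_JITTER,
                                              (spec.m, spec.n))
    raw = _smooth_function(X[:, :spec.n_informative], spec.function,
                           assignment, rng)
    lo, hi = float(raw.min()), float(raw.max())
    span = hi - lo if hi > lo else 1.0
    target = TARGET_WINDOW[0] + (raw - lo) / span * (TARGET_WINDOW[1] - TARGET_WINDOW[0])
    target = target + rng.normal(0.0, spec.noise_sd, spec.m)
    width = len(str(spec.m))
    ids = [f"C{i + 1:0{width}d}" for i in range(spec.m)]
    names = [f"D{i + 1}" for i in range(spec.n)]
    return Dataset(ids=ids, X=X, T=target, descriptor_names=names)


def make_plateau_fixture(k_clusters: int = 4, per_cluster: int = 25,
                         jitter: float = 0.1, slope: float = 1.0,
                         base: float = -5.0, seed: int = 0) -> Dataset:
    """Tight clusters whose targets vary linearly inside each cluster.

    Clusters sit on a square grid in a 2-D descriptor plane, each spread
    uniformly over ``jitter`` in both coordinates, and the target is globally
    linear in the first descriptor: T = base + slope * x1.  A lookup model
    whose neurons each capture one whole cluster can only predict the
    per-cluster mean, so its training RMSE is bounded below by the
    within-cluster target spread (uniform width slope*jitter, sd
    slope*jitter/sqrt(12) ~ 0.029 at the defaults), while a smooth regressor
    can recover the underlying line and do strictly better.
    """
    if k_clusters < 1 or per_cluster < 1:
        raise ConfigurationError("k_clusters and per_cluster must be positive")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(k_clusters)))
    axis = np.linspace(0.25, 0.75, side) if side > 1 else np.array([0.5])
    centers = np.array([(axis[i // side], axis[i % side])
                        for i in range(k_clusters)])
    m = k_clusters * per_cluster
    assignment = np.repeat(np.arange(k_clusters), per_cluster)
    X = centers[assignment] + rng.uniform(-jitter / 2, jitter / 2, (m, 2))
    T = base + slope * X[:, 0]
    width = len(str(m))
    ids = [f"P{i + 1:0{width}d}" for i in range(m)]
    return Dataset(ids=ids, X=X, T=T, descriptor_names=["D1", "D2"])
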