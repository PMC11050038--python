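"""Tabular QSAR datasets: delimited-text I/O, min-max scaling, SOM-based
splitting into train/test/validation sets, and evaluation metrics.

A :class:`Dataset` holds one row per compound: an identifier, ``n`` numeric
molecular-descriptor values, one numeric target property (e.g. logS), and an
optional set-membership label.  Descriptors are consumed as numbers; computing
them from structures is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRAIN = "train"
TEST = "test"
VALIDATION = "validation"
SET_LABELS = (TRAIN, TEST, VALIDATION)


class ConfigurationError(ValueError):
    """A caller-supplied setting is inconsistent or refers to missing columns."""


class DataError(ValueError):
    """The data themselves are malformed (non-numeric cells, duplicate ids...)."""


@dataclass
class Dataset:
    """m compounds x n descriptors with a target vector and optional set labels.

    Invariants enforced at construction: m >= 1, n >= 1, no missing values in
    X or T, unique ids, unique descriptor names.
    """

    ids: list[str]
    X: np.ndarray
    T: np.ndarray
    descriptor_names: list[str]
    set_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.X.ndim != 2:
            raise DataError("descriptor matrix must be two-dimensional")
        m, n = self.X.shape
        if m < 1 or n < 1:
            raise DataError("dataset must contain at least one compound and one descriptor")
        if self.T.shape != (m,):
            raise DataError(f"target vector length {self.T.shape} does not match m={m}")
        if not np.isfinite(self.X).all():
            raise DataError("descriptor matrix contains missing or non-finite values")
        if not np.isfinite(self.T).all():
            raise DataError("target vector contains missing or non-finite values")
        if len(self.ids) != m:
            raise DataError("number of ids does not match number of rows")
        if len(set(self.ids)) != m:
            raise DataError("compound ids must be unique")
        if len(self.descriptor_names) != n:
            raise DataError("number of descriptor names does not match n")
        if len(set(self.descriptor_names)) != n:
            raise DataError("descriptor names must be unique")
        if self.set_labels is not None:
            if len(self.set_labels) != m:
                raise DataError("set_labels length does not match m")
            bad = sorted({s for s in self.set_labels if s not in SET_LABELS})
            if bad:
                raise DataError(f"unknown set labels: {bad}")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def subset(self, label: str) -> "Dataset":
        """Rows carrying the given set label, as a new Dataset (labels kept)."""
        if self.set_labels is None:
            raise ConfigurationError("dataset has no set labels; run som_split first")
        idx = [i for i, s in enumerate(self.set_labels) if s == label]
        if not idx:
            raise ConfigurationError(f"no compounds labelled {label!r}")
        return Dataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            T=self.T[idx],
            descriptor_names=list(self.descriptor_names),
            set_labels=[self.set_labels[i] for i in idx],
        )

    def with_labels(self, labels: Sequence[str]) -> "Dataset":
        return replace(self, set_labels=list(labels))

    def to_frame(self, id_col: str = "id", target_col: str = "target",
                 set_col: str = "set") -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.descriptor_names)
        frame.insert(0, id_col, self.ids)
        frame[target_col] = self.T
        if self.set_labels is not None:
            frame[set_col] = self.set_labels
        return frame


def read_dataset(path: str | Path, id_col: str = "id", target_col: str = "target",
                 set_col: str | None = None, sep: str | None = None) -> Dataset:
    """Read a delimited-text descriptor table into a :class:`Dataset`.

    All columns other than ``id_col``, ``target_col`` and ``set_col`` are
    descriptors and must be numeric; a non-numeric or missing cell is a
    :class:`DataError` naming the offending row and column, never silently
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in [id_col, target_col] + ([set_col] if set_col else []):
        if col not in raw.columns:
            raise ConfigurationError(f"column {col!r} not found in {path.name} "
                                     f"(columns: {list(raw.columns)})")
    ids = raw[id_col].tolist()
    dup = raw[id_col][raw[id_col].duplicated()].tolist()
    if dup:
        raise DataError(f"duplicate compound ids: {sorted(set(dup))}")
    meta = {id_col, target_col} | ({set_col} if set_col else set())
    descriptor_names = [c for c in raw.columns if c not in meta]
    if not descriptor_names:
        raise DataError("no descriptor columns found")

    def numeric(col: str) -> np.ndarray:
        values = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            row = int(bad[0])
            raise DataError(
                f"non-numeric or missing value {raw[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 2} of {path.name} (compound {ids[row]!r})")
        return values.to_numpy(dtype=float)

    X = np.column_stack([numeric(c) for c in descriptor_names])
    T = numeric(target_col)
    labels = None
    if set_col:
        labels = [s.strip().lower() for s in raw[set_col].tolist()]
        bad_labels = sorted({s for s in labels if s not in SET_LABELS})
        if bad_labels:
            raise DataError(f"unknown set labels in column {set_col!r}: {bad_labels}")
    return Dataset(ids=ids, X=X, T=T, descriptor_names=descriptor_names,
                   set_labels=labels)


def write_dataset(dataset: Dataset, path: str | Path, id_col: str = "id",
                  target_col: str = "target", set_col: str = "set",
                  sep: str | None = None) -> None:
    """Write a Dataset as delimited text (full float precision, round-trip safe)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    dataset.to_frame(id_col=id_col, target_col=target_col, set_col=set_col).to_csv(
        path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Min-max scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingParams:
    """Per-column min/max of the fitted (training) data plus the scaled target
    interval.  Descriptors map linearly onto [0, 1]; the target onto
    [target_low, target_high] so a sigmoid output neuron can represent every
    training value with headroom.  Values outside the fitted range map outside
    [0, 1] - there is no clipping, so extrapolation stays visible to the
    applicability-domain check.
    """

    x_min: np.ndarray
    x_max: np.ndarray
    t_min: float
    t_max: float
    target_low: float = 0.1
    target_high: float = 0.9

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape or self.x_min.ndim != 1:
            raise ConfigurationError("x_min/x_max must be 1-D and of equal length")
        if np.any(self.x_max < self.x_min) or self.t_max < self.t_min:
            raise ConfigurationError("per-column max must be >= min")
        if not (0.0 <= self.target_low < self.target_high <= 1.0):
            raise ConfigurationError("need 0 <= target_low < target_high <= 1")

    @property
    def n(self) -> int:
        return self.x_min.size

    @property
    def constant_mask(self) -> np.ndarray:
        """Columns where max == min; these scale to 0.5 rather than being dropped."""
        return self.x_max == self.x_min


def fit_scaling(dataset: Dataset, target_low: float = 0.1,
                target_high: float = 0.9) -> ScalingParams:
    """Record per-column min/max of X and T from this dataset only.

    Fit on the training set and reuse the returned params everywhere else;
    never refit on test or validation data.
    """
    params = ScalingParams(
        x_min=dataset.X.min(axis=0), x_max=dataset.X.max(axis=0),
        t_min=float(dataset.T.min()), t_max=float(dataset.T.max()),
        target_low=target_low, target_high=target_high)
    if params.constant_mask.any():
        import warnings
        names = [dataset.descriptor_names[i] for i in np.nonzero(params.constant_mask)[0]]
        warnings.warn(f"constant descriptor columns scaled to 0.5: {names}",
                      stacklevel=2)
    return params


def scale_matrix(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n:
        raise ConfigurationError(
            f"descriptor count {X.shape[1]} does not match fitted n={params.n}")
    span = params.x_max - params.x_min
    const = params.constant_mask
    safe = np.where(const, 1.0, span)
    scaled = (X - params.x_min) / safe
    scaled[:, const] = 0.5
    return scaled


def scale_vector(x: np.ndarray, params: ScalingParams) -> np.ndarray:
    return scale_matrix(np.asarray(x, dtype=float).reshape(1, -1), params)[0]


def scale_target(t: np.ndarray | float, params: ScalingParams) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    span = params.t_max - params.t_min
    lo, hi = params.target_low, params.target_high
    if span == 0.0:  # degenerate constant target: map to the interval midpoint
        return np.full_like(t, 0.5 * (lo + hi))
    return lo + (t - params.t_min) / span * (hi - lo)


def inverse_scale_target(values: np.ndarray | float, params: ScalingParams):
    """Map scaled target values back to original property units."""
    values = np.asarray(values, dtype=float)
    span = params.t_max - params.t_min
    lo, hi = params.target_low, params.target_high
    out = params.t_min + (values - lo) / (hi - lo) * span
    return float(out) if out.ndim == 0 else out


def scale(dataset: Dataset, params: ScalingParams) -> Dataset:
    """Scaled copy: descriptors to [0,1] (on the fitted range), target to
    [target_low, target_high].  No clipping."""
    return replace(dataset, X=scale_matrix(dataset.X, params),
                   T=scale_target(dataset.T, params))


# ---------------------------------------------------------------------------
# SOM-based splitting
# ---------------------------------------------------------------------------

def split_quotas(m: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Set sizes for a (train, test, validation) fraction triple.

    TRAIN takes floor(m * f_train); the remainder is divided between TEST and
    VALIDATION in proportion to their fractions, the larger share going to
    TEST when they cannot be matched exactly (1674 at 60/20/20 -> 1004/335/335).
    """
    f_train, f_test, f_val = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must be positive and sum to 1")
    # epsilon guards keep exact products (e.g. 48 * 0.2/0.4) from drifting
    # across the floor/ceil boundary in floating point
    n_train = int(np.floor(m * f_train + 1e-9))
    rem = m - n_train
    n_test = int(np.ceil(rem * f_test / (f_test + f_val) - 1e-9))
    return n_train, n_test, rem - n_test


def som_split(dataset: Dataset, map_rows: int, map_cols: int,
              fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
              seed: int = 0, epochs: int = 60) -> Dataset:
    """Partition compounds into train/test/validation sets uniformly over a
    Kohonen top-map.

    An unsupervised Kohonen map of ``map_rows x map_cols`` is trained on the
    min-max scaled descriptors; compounds are grouped by winning neuron and
    picked round-robin (neurons in row-major order, within a neuron in
    ascending distance-to-neuron order).  Each pick is labelled with the set
    whose quota is relatively least filled (ties TRAIN > TEST > VALIDATION),
    so structurally similar compounds end up spread across all three sets.
    The map should be small enough that several similar compounds excite each
    neuron; this is documented, not enforced.
    """
    from .cpann import CPANNConfig, batch_winners, train_kohonen

    quotas = split_quotas(dataset.m, fractions)
    params = fit_scaling(dataset)
    Xs = scale_matrix(dataset.X, params)
    config = CPANNConfig(map_rows=map_rows, map_cols=map_cols, epochs=epochs,
                         seed=seed)
    weights = train_kohonen(Xs, config)
    winners, distances = batch_winners(weights, Xs)

    # per-neuron occupant queues, ascending distance (stable on ties)
    queues: dict[int, list[int]] = {}
    for j in np.unique(winners):
        occ = np.nonzero(winners == j)[0]
        queues[int(j)] = occ[np.argsort(distances[occ], kind="stable")].tolist()
    occupied = sorted(queues)  # row-major flat indices

    pick_order: list[int] = []
    while len(pick_order) < dataset.m:
        for j in occupied:
            if queues[j]:
                pick_order.append(queues[j].pop(0))

    remaining = list(quotas)
    labels = [""] * dataset.m
    for compound in pick_order:
        deficits = [remaining[i] / quotas[i] if quotas[i] else -1.0 for i in range(3)]
        choice = int(np.argmax(deficits))  # argmax tie-break: train > test > validation
        labels[compound] = SET_LABELS[choice]
        remaining[choice] -= 1
    return dataset.with_labels(labels)


# ---------------------------------------------------------------------------
# Metrics and evaluation report
# ---------------------------------------------------------------------------

def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root-mean-square error of predictions, in target units."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.size != observed.size:
        raise ConfigurationError(
            f"length mismatch: {predicted.size} predictions vs {observed.size} observations")
    if predicted.size < 1:
        raise ConfigurationError("rmse needs at least one value")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


@dataclass
class SetMetrics:
    """Per-set slice of an evaluation: combined-model and Stage I lookup RMSE,
    the RMSE restricted to in-domain compounds, and the domain counts."""

    n: int
    rmse: float
    rmse_cp: float
    rmse_in_domain: float
    n_in_domain: int
    n_out_of_domain: int

    def __post_init__(self) -> None:
        if self.n_in_domain + self.n_out_of_domain != self.n:
            raise ConfigurationError("domain counts must sum to the set size")


@dataclass
class EvaluationReport:
    """RMSE of predictions per set (train/test/validation) in target units."""

    sets: dict[str, SetMetrics] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.sets.items():
            rows.append({"set": name, "n": s.n, "rmse": s.rmse,
                         "rmse_cp": s.rmse_cp, "rmse_in_domain": s.rmse_in_domain,
                         "n_in_domain": s.n_in_domain,
                         "n_out_of_domain": s.n_out_of_domain})
        return pd.DataFrame(rows)

    @property
    def rmse_train(self) -> float:
        return self.sets[TRAIN].rmse

    @property
    def rmse_test(self) -> float:
        return self.sets[TEST].rmse

    @property
    def rmse_validation(self) -> float:
        return self.sets[VALIDATION].rmse
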