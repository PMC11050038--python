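"""The combined two-stage model: orchestration, selection, evaluation, I/O.

Stage I trains a counter-propagation network on the training compounds;
its k neurons (Kohonen weight vector, Grossberg value) are then extracted
and become the entire training set of Stage II, a back-propagation network.
Stage I is frozen during Stage II - no gradient ever reaches the Kohonen
weights - and the applicability domain is fixed by Stage I alone.  The
deployable predictor therefore pairs a lookup model (robust, at most one
value per neuron) with a smooth regressor (continuous values), sharing one
set of scaling parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import applicability as ad_mod
from .bpe import (BPEConfig, BPENetwork, predict_bpe, predict_bpe_batch,
                  train_bpe)
from .cpann import (CPANNConfig, CPANNModel, extract_neurons, find_winner,
                    predict_cpann_batch, train_cpann)
from .data import (ConfigurationError, Dataset, EvaluationReport,
                   ScalingParams, SetMetrics, fit_scaling,
                   inverse_scale_target, rmse, scale, scale_matrix,
                   scale_vector)

FORMAT_VERSION = "1.0"


@dataclass
class CPBPEModel:
    """Deployable two-stage predictor: CP-ANN + BPE network + shared scaling
    + applicability-domain threshold."""

    cpann: CPANNModel
    bpe: BPENetwork
    scaling: ScalingParams
    ad: ad_mod.ADThreshold
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bpe.n_inputs != self.cpann.n:
            raise ConfigurationError(
                f"Stage II input size {self.bpe.n_inputs} does not equal the "
                f"descriptor count n={self.cpann.n}")


@dataclass
class PredictionRecord:
    """One prediction: the continuous Stage II value, the Stage I lookup
    value (both in target units), the winning neuron, the distance to it in
    scaled space, and the applicability-domain flag."""

    value: float
    cp_value: float
    winner: tuple[int, int]
    distance: float
    in_domain: bool


def train_cpbpe(train: Dataset, cp_config: CPANNConfig, bpe_config: BPEConfig,
                target_low: float = 0.1, target_high: float = 0.9,
                ad_method: str = "max", ad_percentile: float = 95.0,
                occupied_only: bool = False) -> CPBPEModel:
    """Train the combined model on raw training compounds.

    Fits min-max scaling on ``train`` only, trains the CP-ANN on the scaled
    data, extracts all k neurons, trains the BPE network on them, and derives
    the applicability-domain threshold from the training distances.
    """
    scaling = fit_scaling(train, target_low=target_low, target_high=target_high)
    cpann = train_cpann(scale(train, scaling), cp_config, scaling=scaling)
    neurons = extract_neurons(cpann, occupied_only=occupied_only)
    bpe = train_bpe(neurons, bpe_config)
    threshold = ad_mod.fit_ad(cpann.train_distances, method=ad_method,
                              percentile=ad_percentile)
    return CPBPEModel(cpann=cpann, bpe=bpe, scaling=scaling, ad=threshold,
                      metadata={"format_version": FORMAT_VERSION,
                                "stage2_training_objects": neurons.k})


def predict(model: CPBPEModel, x: np.ndarray) -> PredictionRecord:
    """Predict one raw descriptor vector with both stages.

    ``value`` comes from the Stage II network (continuous); ``cp_value`` is
    the Stage I lookup reported alongside for comparison.
    """
    xs = scale_vector(x, model.scaling)
    row, col, dist = find_winner(model.cpann.kohonen, xs)
    cp_value = inverse_scale_target(float(model.cpann.grossberg[row, col]),
                                    model.scaling)
    value = inverse_scale_target(predict_bpe(model.bpe, xs), model.scaling)
    return PredictionRecord(value=value, cp_value=cp_value, winner=(row, col),
                            distance=dist,
                            in_domain=dist <= model.ad.threshold)


def predict_batch(model: CPBPEModel, X: np.ndarray) -> pd.DataFrame:
    """Vectorised prediction over rows of raw descriptors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = scale_matrix(X, model.scaling)
    cp_values, winners, distances = predict_cpann_batch(model.cpann, X)
    values = inverse_scale_target(predict_bpe_batch(model.bpe, Xs), model.scaling)
    cols = model.cpann.config.map_cols
    return pd.DataFrame({
        "predicted": values,
        "cp_predicted": cp_values,
        "winner_row": winners // cols,
        "winner_col": winners % cols,
        "distance": distances,
        "in_domain": distances <= model.ad.threshold,
    })


def predict_table(model: CPBPEModel, dataset: Dataset) -> pd.DataFrame:
    """Prediction table for a Dataset, including ids and observed values."""
    table = predict_batch(model, dataset.X)
    table.insert(0, "id", dataset.ids)
    table.insert(1, "observed", dataset.T)
    return table


# ---------------------------------------------------------------------------
# Model selection and evaluation
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Grid-search outcome: per-cell test RMSE, the chosen cell (minimal test
    RMSE; ties resolved to fewer hidden neurons, then fewer epochs), and the
    retained model."""

    grid: pd.DataFrame
    chosen_hidden: int
    chosen_epochs: int
    model: CPBPEModel
    reports: dict[tuple[int, int], EvaluationReport] = field(default_factory=dict)


def select_model(train: Dataset, test: Dataset, cp_config: CPANNConfig,
                 hidden_grid: list[int], epoch_grid: list[int],
                 bpe_base: BPEConfig | None = None,
                 target_low: float = 0.1, target_high: float = 0.9,
                 ad_method: str = "max", ad_percentile: float = 95.0
                 ) -> SelectionResult:
    """Grid search over Stage II architecture/epochs by test-set RMSE.

    Stage I is trained once and reused across the whole grid - the extracted
    neurons do not depend on Stage II settings.  The validation set is never
    consulted here.
    """
    if not hidden_grid or not epoch_grid:
        raise ConfigurationError("hidden and epoch grids must be nonempty")
    if test.m < 1:
        raise ConfigurationError("model selection needs a nonempty test set")
    if bpe_base is None:
        bpe_base = BPEConfig(hidden_neurons=hidden_grid[0])
    scaling = fit_scaling(train, target_low=target_low, target_high=target_high)
    cpann = train_cpann(scale(train, scaling), cp_config, scaling=scaling)
    neurons = extract_neurons(cpann)
    threshold = ad_mod.fit_ad(cpann.train_distances, method=ad_method,
                              percentile=ad_percentile)
    Xs_test = scale_matrix(test.X, scaling)

    rows = []
    best = None
    for hidden in hidden_grid:
        for epochs in epoch_grid:
            config = BPEConfig(hidden_neurons=hidden,
                               learning_rate=bpe_base.learning_rate,
                               momentum=bpe_base.momentum, epochs=epochs,
                               seed=bpe_base.seed,
                               init_range=bpe_base.init_range,
                               output_activation=bpe_base.output_activation)
            net = train_bpe(neurons, config)
            pred = inverse_scale_target(predict_bpe_batch(net, Xs_test), scaling)
            test_rmse = rmse(pred, test.T)
            rows.append({"hidden_neurons": hidden, "epochs": epochs,
                         "test_rmse": test_rmse})
            key = (test_rmse, hidden, epochs)
            if best is None or key < best[0]:
                best = (key, net)
    (_, chosen_hidden, chosen_epochs), net = best
    model = CPBPEModel(cpann=cpann, bpe=net, scaling=scaling, ad=threshold,
                       metadata={"format_version": FORMAT_VERSION,
                                 "stage2_training_objects": neurons.k,
                                 "selection": {"hidden": chosen_hidden,
                                               "epochs": chosen_epochs}})
    return SelectionResult(grid=pd.DataFrame(rows), chosen_hidden=chosen_hidden,
                           chosen_epochs=chosen_epochs, model=model)


def evaluate(model: CPBPEModel, dataset: Dataset) -> EvaluationReport:
    """Per-set RMSE report on a labelled dataset.

    Each present set gets the combined-model RMSE, the Stage I lookup RMSE,
    and the combined-model RMSE restricted to in-domain compounds (NaN when a
    set has no in-domain members).  Absent sets are omitted with a notice.
    """
    import warnings

    if dataset.set_labels is None:
        raise ConfigurationError("evaluate needs a dataset with set labels")
    report = EvaluationReport()
    for label in ("train", "test", "validation"):
        if label not in dataset.set_labels:
            warnings.warn(f"no compounds labelled {label!r}; omitted from report",
                          stacklevel=2)
            continue
        part = dataset.subset(label)
        table = predict_table(model, part)
        flags = table["in_domain"].to_numpy()
        in_rmse = rmse(table["predicted"][flags], part.T[flags]) \
            if flags.any() else float("nan")
        report.sets[label] = SetMetrics(
            n=part.m,
            rmse=rmse(table["predicted"], part.T),
            rmse_cp=rmse(table["cp_predicted"], part.T),
            rmse_in_domain=in_rmse,
            n_in_domain=int(flags.sum()),
            n_out_of_domain=int((~flags).sum()))
    return report


def crossvalidate(train: Dataset, leave_out: int, cp_config: CPANNConfig,
                  bpe_config: BPEConfig, seed: int = 0) -> float:
    """Leave-k-out cross-validation RMSE of the combined model.

    Compounds are shuffled once from the seed and held out in contiguous
    blocks of ``leave_out`` (the last block may be smaller); both stages are
    retrained on each fold's remainder; the pooled held-out predictions are
    scored by RMSE in target units.
    """
    if leave_out <= 0:
        raise ConfigurationError("leave_out must be positive")
    if leave_out >= train.m:
        raise ConfigurationError("leave_out must be smaller than the training set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(train.m)
    predictions = np.empty(train.m)
    for start in range(0, train.m, leave_out):
        held = order[start:start + leave_out]
        kept = np.concatenate([order[:start], order[start + leave_out:]])
        fold = Dataset(ids=[train.ids[i] for i in kept], X=train.X[kept],
                       T=train.T[kept],
                       descriptor_names=list(train.descriptor_names))
        model = train_cpbpe(fold, cp_config, bpe_config)
        predictions[held] = predict_batch(model, train.X[held])["predicted"]
    return rmse(predictions, train.T)


# ---------------------------------------------------------------------------
# Persistence (single JSON document, versioned)
# ---------------------------------------------------------------------------

def _array(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": a.ravel().tolist(),
            "dtype": "int" if np.issubdtype(a.dtype, np.integer) else "float"}


def _unarray(d: dict) -> np.ndarray:
    dtype = int if d["dtype"] == "int" else float
    return np.asarray(d["data"], dtype=dtype).reshape(d["shape"])


def model_to_dict(model: CPBPEModel) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "scaling": {"x_min": model.scaling.x_min.tolist(),
                    "x_max": model.scaling.x_max.tolist(),
                    "t_min": model.scaling.t_min, "t_max": model.scaling.t_max,
                    "target_low": model.scaling.target_low,
                    "target_high": model.scaling.target_high},
        "cpann": {"config": asdict(model.cpann.config),
                  "kohonen": _array(model.cpann.kohonen),
                  "grossberg": _array(model.cpann.grossberg),
                  "train_distances": _array(model.cpann.train_distances),
                  "occupancy": _array(model.cpann.occupancy)},
        "bpe": {"config": asdict(model.bpe.config),
                "w_hidden": _array(model.bpe.w_hidden),
                "w_out": _array(model.bpe.w_out),
                "prev_dw_hidden": _array(model.bpe.prev_dw_hidden),
                "prev_dw_out": _array(model.bpe.prev_dw_out),
                "rmse_trace": _array(model.bpe.rmse_trace)},
        "ad": {"threshold": model.ad.threshold, "method": model.ad.method,
               "percentile": model.ad.percentile},
        "metadata": model.metadata,
    }


def save_model(model: CPBPEModel, path: str | Path) -> None:
    """Serialize to a single JSON document.  Identical models (same data,
    configs and seeds) produce byte-identical files."""
    Path(path).write_text(json.dumps(model_to_dict(model), sort_keys=True,
                                     separators=(",", ":")) + "\n")


def load_model(path: str | Path) -> CPBPEModel:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version", "")
    try:
        major = int(str(version).split(".")[0])
    except ValueError:
        raise ConfigurationError(f"unrecognised model format version {version!r}")
    if major > int(FORMAT_VERSION.split(".")[0]):
        raise ConfigurationError(
            f"model format {version} is newer than supported ({FORMAT_VERSION})")
    scaling = ScalingParams(x_min=np.asarray(doc["scaling"]["x_min"]),
                            x_max=np.asarray(doc["scaling"]["x_max"]),
                            t_min=doc["scaling"]["t_min"],
                            t_max=doc["scaling"]["t_max"],
                            target_low=doc["scaling"]["target_low"],
                            target_high=doc["scaling"]["target_high"])
    cp = doc["cpann"]
    cpann = CPANNModel(kohonen=_unarray(cp["kohonen"]),
                       grossberg=_unarray(cp["grossberg"]),
                       config=CPANNConfig(**cp["config"]), scaling=scaling,
                       train_distances=_unarray(cp["train_distances"]),
                       occupancy=_unarray(cp["occupancy"]))
    bp = doc["bpe"]
    bpe = BPENetwork(w_hidden=_unarray(bp["w_hidden"]),
                     w_out=_unarray(bp["w_out"]),
                     prev_dw_hidden=_unarray(bp["prev_dw_hidden"]),
                     prev_dw_out=_unarray(bp["prev_dw_out"]),
                     config=BPEConfig(**bp["config"]),
                     rmse_trace=_unarray(bp["rmse_trace"]))
    threshold = ad_mod.ADThreshold(**doc["ad"])
    return CPBPEModel(cpann=cpann, bpe=bpe, scaling=scaling, ad=threshold,
                      metadata=doc.get("metadata", {}))
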