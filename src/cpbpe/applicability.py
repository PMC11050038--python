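"""Applicability-domain (AD) assessment.

A QSAR model should only be used to interpolate within the descriptor space
its training set covers.  Here the domain is defined from the distribution of
the training compounds' Euclidean distances (in scaled descriptor space) to
their excited Kohonen neurons: a query whose distance to its winning neuron
exceeds a threshold derived from that distribution is flagged out of domain.
The check is a Stage I property only - retraining the back-propagation stage
never changes any flag, because Stage II is trained on the neurons themselves.
Out-of-domain compounds still receive predictions; the flag marks them
unreliable rather than suppressing them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpann import batch_winners, find_winner
from .data import ConfigurationError, Dataset, scale_matrix, scale_vector


@dataclass
class ADThreshold:
    """Distance threshold in scaled descriptor space.

    method "max": the maximum training distance (most permissive rule
    consistent with using the distance distribution; every training compound
    is in domain by construction).  method "percentile": the given percentile
    of training distances, linearly interpolated between order statistics.
    """

    threshold: float
    method: str = "max"
    percentile: float | None = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.method not in ("max", "percentile"):
            raise ConfigurationError("method must be 'max' or 'percentile'")
        if self.method == "percentile":
            if self.percentile is None or not (0 < self.percentile <= 100):
                raise ConfigurationError("percentile must lie in (0, 100]")


def fit_ad(train_distances: np.ndarray, method: str = "max",
           percentile: float = 95.0) -> ADThreshold:
    """Derive the domain threshold from training-compound distances."""
    d = np.asarray(train_distances, dtype=float)
    if d.size == 0:
        raise ConfigurationError("cannot fit an applicability domain on no distances")
    if np.any(d < 0):
        raise ConfigurationError("distances must be nonnegative")
    if method == "max":
        return ADThreshold(threshold=float(d.max()), method="max")
    return ADThreshold(threshold=float(np.percentile(d, percentile)),
                       method="percentile", percentile=percentile)


def in_domain(model, x: np.ndarray) -> tuple[bool, float]:
    """Flag one raw descriptor vector: (distance <= threshold, distance)."""
    xs = scale_vector(x, model.scaling)
    _r, _c, dist = find_winner(model.cpann.kohonen, xs)
    return dist <= model.ad.threshold, dist


def in_domain_batch(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`in_domain` over rows of raw descriptors."""
    Xs = scale_matrix(X, model.scaling)
    _winners, distances = batch_winners(model.cpann.kohonen, Xs)
    return distances <= model.ad.threshold, distances


def outlier_report(model, dataset: Dataset) -> pd.DataFrame:
    """Out-of-domain compounds with their experimental value and both model
    predictions (columns: id, experimental, pred_cpann, pred_cpbpe, distance).
    An empty table is a valid result."""
    from .model import predict_table

    table = predict_table(model, dataset)
    out = table[~table["in_domain"]]
    return pd.DataFrame({
        "id": out["id"],
        "experimental": out["observed"],
        "pred_cpann": out["cp_predicted"],
        "pred_cpbpe": out["predicted"],
        "distance": out["distance"],
    }).reset_index(drop=True)
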