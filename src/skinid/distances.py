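"""Dissimilarity measures between aligned OTU abundance vectors.

The Canberra distance is the core of the identification method:

    D(X, Y) = sum_i |x_i - y_i| / (|x_i| + |y_i|)

Each coordinate contributes at most 1 regardless of magnitude, so a minor
taxon present in one sample and absent in the other adds a full unit —
exactly as much as a disagreement in the dominant taxon. That equal
weighting of rare taxa is what makes the metric discriminative between
individuals whose communities are all dominated by the same species.
Coordinates where both vectors are zero contribute 0 (implementations
differ here; this convention matches R's ``dist(method="canberra")`` as
effectively applied to non-negative data).

Bray–Curtis and presence/absence Jaccard are provided for comparison.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .tables import OtuTable

METRICS = ("canberra", "bray_curtis", "jaccard")


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundance vectors must be non-negative")
    return x, y


def canberra(x: np.ndarray, y: np.ndarray) -> float:
    """Canberra distance; 0/0 coordinates contribute 0."""
    x, y = _check_pair(x, y)
    den = x + y
    mask = den > 0
    num = np.abs(x[mask] - y[mask])
    return float((num / den[mask]).sum())


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity: sum|x−y| / sum(x+y), in [0, 1]."""
    x, y = _check_pair(x, y)
    total = float((x + y).sum())
    if total == 0:
        raise ValueError("Bray–Curtis is undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / total)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Presence/absence Jaccard distance: 1 − |A∩B| / |A∪B| with A, B supports."""
    x, y = _check_pair(x, y)
    a = x > 0
    b = y > 0
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("Jaccard is undefined when both supports are empty")
    inter = int(np.count_nonzero(a & b))
    return 1.0 - inter / union


_PAIR_FUNCS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "canberra": canberra,
    "bray_curtis": bray_curtis,
    "jaccard": jaccard,
}


def get_metric(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    try:
        return _PAIR_FUNCS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; valid metrics: {list(METRICS)}") from None


def _pairwise_rows(X: np.ndarray, metric: str) -> np.ndarray:
    """Dense pairwise distances between rows of X, one broadcast row at a time."""
    n = X.shape[0]
    D = np.zeros((n, n), dtype=float)
    if metric == "jaccard":
        P = X > 0
        for i in range(n):
            inter = np.count_nonzero(P & P[i], axis=1)
            union = np.count_nonzero(P | P[i], axis=1)
            if np.any(union == 0):
                raise ValueError("Jaccard is undefined when both supports are empty")
            D[i] = 1.0 - inter / union
        return D
    for i in range(n):
        diff = np.abs(X - X[i])
        den = X + X[i]
        if metric == "canberra":
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where(den > 0, diff / np.where(den > 0, den, 1.0), 0.0)
            D[i] = terms.sum(axis=1)
        elif metric == "bray_curtis":
            totals = den.sum(axis=1)
            if np.any(totals == 0):
                raise ValueError("Bray–Curtis is undefined for two all-zero vectors")
            D[i] = diff.sum(axis=1) / totals
        else:  # pragma: no cover - guarded by get_metric
            raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_distance_matrix(table: OtuTable, metric: str = "canberra") -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix under ``metric``.

    Returned as a DataFrame labelled by sample id (zero diagonal). This is
    the workhorse of every evaluation experiment: computing it once makes
    leave-one-out and the randomised trials cheap lookups.
    """
    get_metric(metric)  # validate name
    if table.n_samples == 0:
        raise ValueError("table has no samples")
    D = _pairwise_rows(table.matrix(), metric)
    # enforce exact symmetry against float reduction-order noise
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=table.sample_ids, columns=table.sample_ids)


def write_distance_matrix(D: pd.DataFrame, path) -> None:
    """Export a labelled square distance matrix as TSV."""
    out = D.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")
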