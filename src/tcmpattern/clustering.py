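"""K-means clustering of the binary feature matrix with elbow k selection.

Cases are rows of a 0/1 matrix (term present / absent). Distances are plain
Euclidean on the raw values — every variable already shares the binary scale,
so no standardization is applied. The number of clusters is chosen where the
declining slope of the total within-cluster sum of squares moderates,
formalized as the smallest k whose relative WSS drop to k+1 falls below a
configurable threshold (default 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .vocab import CATEGORIES
from .terminology import StandardizedRecord


@dataclass
class BinaryFeatureMatrix:
    """Case x variable 0/1 presence matrix."""

    case_ids: list[str]
    variables: list[tuple[str, str]]  # (term, category)
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.case_ids), len(self.variables)):
            raise ValueError("matrix shape does not match ids/variables")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variables")

    def subset(self, variables: Sequence[tuple[str, str]]) -> "BinaryFeatureMatrix":
        idx = [self.variables.index(v) for v in variables]
        return BinaryFeatureMatrix(
            case_ids=list(self.case_ids),
            variables=list(variables),
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.variables, names=["term", "category"])
        return pd.DataFrame(self.values, index=self.case_ids, columns=cols)


def build_feature_matrix(
    records: Iterable[StandardizedRecord],
    variables: Sequence[tuple[str, str]] | None = None,
) -> BinaryFeatureMatrix:
    """Binary matrix from standardized records.

    ``variables`` fixes the column set/order; by default the union of observed
    (term, category) pairs is used, ordered by category then term.
    """
    records = list(records)
    if variables is None:
        observed: set[tuple[str, str]] = set()
        for r in records:
            for cat, terms in r.terms_by_category().items():
                observed.update((t, cat) for t in terms)
        variables = sorted(observed, key=lambda v: (CATEGORIES.index(v[1]), v[0]))
    variables = list(variables)
    col = {v: j for j, v in enumerate(variables)}
    values = np.zeros((len(records), len(variables)), dtype=np.int8)
    for i, r in enumerate(records):
        for cat, terms in r.terms_by_category().items():
            for t in terms:
                j = col.get((t, cat))
                if j is not None:
                    values[i, j] = 1
    return BinaryFeatureMatrix(
        case_ids=[r.case_id for r in records], variables=variables, values=values
    )


@dataclass
class ClusterModel:
    """Fitted k-means model; cluster labels are 1-based (1..k)."""

    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    total_wss: float
    wss_by_k: dict[int, float] = field(default_factory=dict)

    def labels(self, case_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[c] for c in case_ids])


def kmeans(
    matrix: BinaryFeatureMatrix, k: int, seed: int = 0, restarts: int = 25
) -> ClusterModel:
    """Lloyd k-means, best of ``restarts`` k-means++ initializations by WSS."""
    if k < 2:
        raise ValueError("k must be at least 2")
    n_distinct = len(np.unique(matrix.values, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(matrix.values.astype(float))
    return ClusterModel(
        k=k,
        assignments={cid: int(lab) + 1 for cid, lab in zip(matrix.case_ids, labels)},
        centroids=km.cluster_centers_,
        total_wss=float(km.inertia_),
    )


def wss_curve(
    matrix: BinaryFeatureMatrix,
    k_range: Sequence[int],
    seed: int = 0,
    restarts: int = 25,
) -> dict[int, float]:
    """Total within-cluster sum of squares for each k in ``k_range``."""
    return {
        k: kmeans(matrix, k, seed=seed, restarts=restarts).total_wss
        for k in sorted(k_range)
    }


def elbow_k(wss_by_k: dict[int, float], drop_threshold: float = 0.10) -> int:
    """Smallest k whose relative WSS drop to k+1 falls below the threshold.

    Falls back, with a warning, to the largest tested k when the decline
    never moderates.
    """
    if not wss_by_k:
        raise ValueError("empty WSS curve")
    ks = sorted(wss_by_k)
    for k, k_next in zip(ks, ks[1:]):
        if k_next != k + 1:
            continue
        drop = (wss_by_k[k] - wss_by_k[k_next]) / wss_by_k[k]
        if drop < drop_threshold:
            return k
    warnings.warn(
        "WSS decline never moderated below the drop threshold; "
        "returning the largest tested k",
        stacklevel=2,
    )
    return ks[-1]


def choose_k(
    matrix: BinaryFeatureMatrix,
    k_range: Sequence[int] = range(2, 9),
    drop_threshold: float = 0.10,
    seed: int = 0,
    restarts: int = 25,
) -> tuple[int, dict[int, float]]:
    """Elbow selection of the cluster count; returns (k, wss curve)."""
    ks = sorted(k_range)
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] > 12:
        raise ValueError("k range must lie within [2, 12]")
    curve = wss_curve(matrix, ks, seed=seed, restarts=restarts)
    return elbow_k(curve, drop_threshold=drop_threshold), curve
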