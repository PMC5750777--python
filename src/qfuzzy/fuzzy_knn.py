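"""Fuzzy k-nearest-neighbour classification.

A query's class membership is the distance-weighted convex combination of
its k nearest training samples' membership rows,

    u(x, c) = sum_k u(x_k, c) * d(x, x_k)^(-2/(m-1)) / sum_k d(x, x_k)^(-2/(m-1)),

with Euclidean distances on min–max-normalized features and weight
exponent m > 1. Training memberships are crisp (one-hot) by default; the
formulation accepts any row-stochastic membership matrix, so fuzzified
initializations can be plugged in.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MinMaxParams:
    """Per-column training-fold minima and ranges for min–max scaling."""
    lo: np.ndarray
    span: np.ndarray   # hi - lo; 0 for constant columns


def normalize_fit(features: np.ndarray) -> MinMaxParams:
    """Fit per-column min–max statistics on (training-fold) features."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] < 1:
        raise ValueError("need at least one row")
    lo = features.min(axis=0)
    return MinMaxParams(lo=lo, span=features.max(axis=0) - lo)


def normalize_apply(params: MinMaxParams, features: np.ndarray) -> np.ndarray:
    """Scale columns to [0, 1]; constant columns map to 0, outliers clip."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    span = np.where(params.span > 0, params.span, 1.0)
    scaled = (features - params.lo) / span
    scaled[:, params.span == 0] = 0.0
    return np.clip(scaled, 0.0, 1.0)


def init_memberships(labels: np.ndarray, n_classes: int | None = None, scheme: str = "crisp") -> np.ndarray:
    """Training membership matrix from class labels (crisp = one-hot rows)."""
    if scheme != "crisp":
        raise ValueError(f"unknown membership scheme {scheme!r}")
    labels = np.asarray(labels, dtype=np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    out = np.zeros((labels.size, n_classes), dtype=float)
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# Membership aggregation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MembershipResult:
    """Class memberships of one query plus its neighbourhood."""
    memberships: np.ndarray
    predicted_class: int
    neighbour_ids: np.ndarray
    distances: np.ndarray


def _nearest(distances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest columns per row; ties broken by lower index.

    Fast path uses an unstable sort; rows where a distance tie straddles
    the k-th rank (the only case where stability changes the selected
    *set* — order within the top k never affects the convex aggregation)
    are redone with a stable sort.
    """
    order = np.argsort(distances, axis=1)
    if distances.shape[1] > k:
        top = np.take_along_axis(distances, order[:, k - 1 : k + 1], axis=1)
        straddle = top[:, 0] == top[:, 1]
        if straddle.any():
            order[straddle] = np.argsort(distances[straddle], axis=1, kind="stable")
    return order[:, :k]


def memberships_from_distances(
    distances: np.ndarray,
    train_memberships: np.ndarray,
    k: int,
    m: float = 2.0,
    squared: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate memberships for a (queries × train) distance matrix.

    Returns (memberships, neighbour index matrix). Zero-distance
    neighbours dominate in the limit of the weight formula: such a query
    inherits the mean membership row of its zero-distance neighbours.
    ``squared=True`` declares the matrix to hold squared distances, which
    rank identically and feed the weight d^(−2/(m−1)) = (d²)^(−1/(m−1))
    without a square root.
    """
    if m <= 1:
        raise ValueError(f"weight exponent m must be > 1, got {m}")
    distances = np.atleast_2d(np.asarray(distances, dtype=float))
    n_train = distances.shape[1]
    if k > n_train:
        raise ValueError(f"k={k} exceeds training size {n_train}")
    neigh = _nearest(distances, k)
    d_k = np.take_along_axis(distances, neigh, axis=1)
    u_k = train_memberships[neigh]                      # (q, k, C)

    exponent = -1.0 / (m - 1.0) if squared else -2.0 / (m - 1.0)
    with np.errstate(divide="ignore"):
        w = d_k ** exponent
    zero = d_k == 0.0
    any_zero = zero.any(axis=1)
    w = np.where(zero, 0.0, w)
    # limit of the weight formula: zero-distance rows take all the mass
    w[any_zero] = zero[any_zero].astype(float)
    out = (w[:, :, None] * u_k).sum(axis=1) / w.sum(axis=1, keepdims=True)
    return out, neigh


def membership(
    train_features: np.ndarray,
    train_memberships: np.ndarray,
    query: np.ndarray,
    k: int,
    m: float = 2.0,
) -> MembershipResult:
    """Class memberships of a single query against normalized training data."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    dist = cdist(query, np.atleast_2d(train_features))
    u, neigh = memberships_from_distances(dist, train_memberships, k, m)
    return MembershipResult(
        memberships=u[0],
        predicted_class=int(np.argmax(u[0])),
        neighbour_ids=neigh[0],
        distances=dist[0, neigh[0]],
    )


class FuzzyKNN:
    """Fuzzy k-NN with min–max normalization fit on the training data.

    Parameters
    ----------
    k
        Number of neighbours (2–7 is the useful range on cell features;
        4 tends to be best).
    m
        Fuzzy weight exponent, > 1; 2 is the conventional choice.
    """

    def __init__(self, k: int = 4, m: float = 2.0):
        if m <= 1:
            raise ValueError(f"weight exponent m must be > 1, got {m}")
        self.k = int(k)
        self.m = float(m)
        self._params: MinMaxParams | None = None
        self._train: np.ndarray | None = None
        self._memberships: np.ndarray | None = None
        self.n_classes_: int | None = None

    def fit(self, features: np.ndarray, labels: np.ndarray, n_classes: int | None = None) -> "FuzzyKNN":
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[0] < self.k:
            raise ValueError(f"need at least k={self.k} training rows")
        self._params = normalize_fit(features)
        self._train = normalize_apply(self._params, features)
        self._memberships = init_memberships(labels, n_classes)
        self.n_classes_ = self._memberships.shape[1]
        return self

    def predict_memberships(self, queries: np.ndarray) -> np.ndarray:
        if self._train is None:
            raise RuntimeError("classifier is not fitted")
        q = normalize_apply(self._params, queries)
        dist = cdist(q, self._train)
        u, _ = memberships_from_distances(dist, self._memberships, self.k, self.m)
        return u

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Predicted class per query: argmax membership, lowest index on ties."""
        return np.argmax(self.predict_memberships(queries), axis=1)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        state = {
            "k": self.k,
            "m": self.m,
            "lo": self._params.lo.tolist(),
            "span": self._params.span.tolist(),
            "train": self._train.tolist(),
            "memberships": self._memberships.tolist(),
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def from_json(cls, path: str | Path) -> "FuzzyKNN":
        state = json.loads(Path(path).read_text())
        model = cls(k=state["k"], m=state["m"])
        model._params = MinMaxParams(
            lo=np.asarray(state["lo"]), span=np.asarray(state["span"])
        )
        model._train = np.asarray(state["train"])
        model._memberships = np.asarray(state["memberships"])
        model.n_classes_ = model._memberships.shape[1]
        return model


def predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    k: int,
    m: float = 2.0,
) -> np.ndarray:
    """One-shot normalized Fuzzy k-NN prediction for a batch of queries."""
    return FuzzyKNN(k=k, m=m).fit(train_features, train_labels).predict(queries)
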