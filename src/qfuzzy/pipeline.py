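"""The Q-Fuzzy / P-Fuzzy wrapper: swarm-searched feature subsets scored by
cross-validated Fuzzy k-NN macro-F1.

A particle's bit mask selects feature-vector entries; its fitness is the
mean macro-F1 of a Fuzzy k-NN classifier over seeded stratified folds
using only those entries (the all-zero mask scores 0 by convention).
Fold assignment, fold-wise min–max normalization and the classifier all
live behind :class:`CrossValFitness`, which precomputes per-fold column
difference tensors so that a mask evaluation is a single tensor
contraction — the optimizer calls it tens of thousands of times.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fuzzy_knn
from .evaluation import metrics_report, stratified_kfold
from .swarm import OptimizerConfig, SwarmResult, run_pso, run_qpso


class CrossValFitness:
    """Deterministic subset-fitness function over a fixed feature table.

    For each stratified fold the training-fold min–max normalization is
    fit once on all columns (column-wise, so it is unaffected by which
    subset a mask later selects) and the per-column squared differences
    between test and training rows are cached; a mask evaluation then
    contracts the cache with the mask, ranks neighbours and aggregates
    fuzzy memberships. Identical masks always yield identical fitness, and
    results are memoized.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        k: int = 4,
        m: float = 2.0,
        n_folds: int = 5,
        seed: int = 0,
    ):
        features = np.atleast_2d(np.asarray(features, dtype=float))
        labels = np.asarray(labels, dtype=np.int64)
        if features.shape[0] != labels.size:
            raise ValueError("features and labels disagree on sample count")
        self.n_dimensions = features.shape[1]
        self.k, self.m, self.n_folds, self.seed = int(k), float(m), int(n_folds), int(seed)
        self.n_classes = int(labels.max()) + 1
        self.folds = stratified_kfold(labels, n_folds, seed)
        self._cache: dict[bytes, float] = {}
        self._fold_data = []
        all_idx = np.arange(labels.size)
        for test_idx in self.folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            params = fuzzy_knn.normalize_fit(features[train_idx])
            train = fuzzy_knn.normalize_apply(params, features[train_idx])
            test = fuzzy_knn.normalize_apply(params, features[test_idx])
            diff_sq = (test[:, None, :] - train[None, :, :]) ** 2
            self._fold_data.append({
                # flattened (n_test*n_train, d) view: a mask evaluation is one
                # fixed-order contraction (einsum, not BLAS, so results do not
                # depend on thread count or vendor reduction order)
                "diff_sq": np.ascontiguousarray(diff_sq.reshape(-1, diff_sq.shape[2])),
                "shape": diff_sq.shape[:2],
                "train_memberships": fuzzy_knn.init_memberships(labels[train_idx], self.n_classes),
                "true": labels[test_idx],
            })

    def _fold_predictions(self, mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """(true, predicted) per fold for the masked feature subset."""
        out = []
        for fold in self._fold_data:
            dist_sq = np.einsum(
                "nd,d->n", fold["diff_sq"], mask, optimize=False
            ).reshape(fold["shape"])
            u, _ = fuzzy_knn.memberships_from_distances(
                dist_sq, fold["train_memberships"], self.k, self.m, squared=True
            )
            out.append((fold["true"], np.argmax(u, axis=1)))
        return out

    def _fast_macro_f1(self, true: np.ndarray, pred: np.ndarray) -> float:
        """Vectorized macro-F1 over all classes (matches evaluation.macro_f1)."""
        C = self.n_classes
        tp = np.bincount(true[true == pred], minlength=C).astype(float)
        n_pred = np.bincount(pred, minlength=C).astype(float)
        n_true = np.bincount(true, minlength=C).astype(float)
        p = np.divide(tp, n_pred, out=np.zeros(C), where=n_pred > 0)
        r = np.divide(tp, n_true, out=np.zeros(C), where=n_true > 0)
        pr = p + r
        f1 = np.divide(2 * p * r, pr, out=np.zeros(C), where=pr > 0)
        return float(f1.mean())

    def __call__(self, mask) -> float:
        mask = np.asarray(mask, dtype=float)
        if mask.size != self.n_dimensions:
            raise ValueError(f"mask length {mask.size} != {self.n_dimensions} features")
        if not mask.any():
            return 0.0       # empty subset carries no information
        key = mask.astype(np.int8).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        scores = [
            self._fast_macro_f1(true, pred) for true, pred in self._fold_predictions(mask)
        ]
        value = float(np.mean(scores))
        self._cache[key] = value
        return value

    def pooled_report(self, mask) -> dict:
        """Final metrics from fold-pooled predictions (per-class P/R/F1, κ)."""
        mask = np.asarray(mask, dtype=float)
        pairs = self._fold_predictions(mask)
        true = np.concatenate([t for t, _ in pairs])
        pred = np.concatenate([p for _, p in pairs])
        return metrics_report(true, pred, list(range(self.n_classes)))


def subset_fitness(
    features: np.ndarray,
    labels: np.ndarray,
    mask,
    k: int = 4,
    m: float = 2.0,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated Fuzzy k-NN macro-F1 of one feature subset."""
    return CrossValFitness(features, labels, k=k, m=m, n_folds=n_folds, seed=seed)(mask)


@dataclasses.dataclass
class SelectionResult:
    """Outcome of a wrapper feature-selection run."""
    best_mask: np.ndarray
    selected_names: list[str]
    best_fitness: float
    n_selected: int
    trace: np.ndarray
    report: dict                 # pooled-fold metrics of the final subset
    all_features_report: dict    # same metrics with every feature retained
    optimizer: str
    n_evaluations: int

    def to_json(self, path: str | Path, config: dict | None = None) -> None:
        payload = {
            "optimizer": self.optimizer,
            "best_mask": self.best_mask.astype(int).tolist(),
            "selected_names": self.selected_names,
            "best_fitness": self.best_fitness,
            "n_selected": self.n_selected,
            "trace": self.trace.tolist(),
            "report": self.report,
            "all_features_report": self.all_features_report,
            "n_evaluations": self.n_evaluations,
        }
        if config is not None:
            payload["config"] = config
        Path(path).write_text(json.dumps(payload, indent=2))


def select_features(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    optimizer: str = "qpso",
    config: OptimizerConfig | None = None,
    k: int = 4,
    m: float = 2.0,
    n_folds: int = 5,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Run the Q-Fuzzy (``optimizer="qpso"``) or P-Fuzzy (``"pso"``) wrapper.

    The particle length equals the table width; the returned mask is the
    global-best subset, reported together with pooled-fold metrics for the
    selected subset and for the all-features baseline.
    """
    if isinstance(features, pd.DataFrame):
        if feature_names is None:
            feature_names = list(features.columns)
        features = features.to_numpy(dtype=float)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(features.shape[1])]
    if config is None:
        config = OptimizerConfig()

    fitness = CrossValFitness(features, labels, k=k, m=m, n_folds=n_folds, seed=config.seed)
    runner = {"qpso": run_qpso, "pso": run_pso}.get(optimizer)
    if runner is None:
        raise ValueError(f"optimizer must be 'qpso' or 'pso', got {optimizer!r}")
    swarm: SwarmResult = runner(fitness, features.shape[1], config)

    mask = swarm.best_mask
    return SelectionResult(
        best_mask=mask,
        selected_names=[feature_names[i] for i in np.flatnonzero(mask)],
        best_fitness=swarm.best_fitness,
        n_selected=int(mask.sum()),
        trace=swarm.trace,
        report=fitness.pooled_report(mask),
        all_features_report=fitness.pooled_report(np.ones(features.shape[1])),
        optimizer=optimizer,
        n_evaluations=swarm.n_evaluations,
    )
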