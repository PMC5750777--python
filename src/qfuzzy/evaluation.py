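"""Classification evaluation: per-class precision/recall/F1, Cohen's kappa
and seeded stratified k-fold utilities.

Multi-class precision and recall are computed one-vs-rest per class,

    P = tp / (tp + fp),   R = tp / (tp + fn),   F1 = 2 P R / (P + R),

with macro (unweighted class mean) aggregates. A degenerate denominator
yields 0 rather than NaN. Cohen's kappa is the chance-corrected agreement
κ = (p_o − p_e) / (1 − p_e) with p_e the product-of-marginals chance rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest tp/fp/fn counts."""
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_samples: int
    class_names: list

    @classmethod
    def from_labels(cls, true_labels, predicted_labels, class_names=None) -> "ConfusionCounts":
        true_labels = np.asarray(true_labels)
        predicted_labels = np.asarray(predicted_labels)
        if true_labels.shape != predicted_labels.shape or true_labels.size == 0:
            raise ValueError("label vectors must be equal-length and non-empty")
        if class_names is None:
            class_names = sorted(np.unique(np.concatenate([true_labels, predicted_labels])).tolist())
        tp, fp, fn = [], [], []
        for c in class_names:
            tp.append(int(((true_labels == c) & (predicted_labels == c)).sum()))
            fp.append(int(((true_labels != c) & (predicted_labels == c)).sum()))
            fn.append(int(((true_labels == c) & (predicted_labels != c)).sum()))
        return cls(np.array(tp), np.array(fp), np.array(fn), true_labels.size, list(class_names))


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(counts: ConfusionCounts) -> pd.DataFrame:
    """Per-class P/R/F1 table plus a ``macro`` row of unweighted means."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts.tp + counts.fp > 0, counts.tp / np.maximum(counts.tp + counts.fp, 1), 0.0)
        r = np.where(counts.tp + counts.fn > 0, counts.tp / np.maximum(counts.tp + counts.fn, 1), 0.0)
    f1 = np.array([f1_from_pr(pi, ri) for pi, ri in zip(p, r)])
    table = pd.DataFrame(
        {"precision": p, "recall": r, "f1": f1},
        index=pd.Index(counts.class_names, name="class"),
    )
    table.loc["macro"] = [p.mean(), r.mean(), f1.mean()]
    return table


def macro_f1(true_labels, predicted_labels, class_names=None) -> float:
    counts = ConfusionCounts.from_labels(true_labels, predicted_labels, class_names)
    return float(precision_recall_f1(counts).loc["macro", "f1"])


@dataclasses.dataclass(frozen=True)
class AgreementSummary:
    po: float      # observed agreement
    pe: float      # chance agreement from the raters' marginals
    kappa: float


def cohen_kappa(true_labels, predicted_labels) -> AgreementSummary:
    """Chance-corrected agreement between two label vectors.

    When both raters are constant and identical (p_e = 1) agreement is
    perfect and κ is defined as 1.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape or true_labels.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    n = true_labels.size
    po = float((true_labels == predicted_labels).mean())
    classes = np.unique(np.concatenate([true_labels, predicted_labels]))
    pe = float(
        sum(
            (true_labels == c).sum() / n * (predicted_labels == c).sum() / n
            for c in classes
        )
    )
    if pe == 1.0:
        if po == 1.0:
            return AgreementSummary(po=po, pe=pe, kappa=1.0)
        raise ValueError("chance agreement is 1 but raters disagree")
    return AgreementSummary(po=po, pe=pe, kappa=(po - pe) / (1.0 - pe))


def stratified_kfold(labels, r: int, seed: int) -> list[np.ndarray]:
    """r disjoint, label-stratified index folds, reproducible from the seed.

    Within each class the (shuffled) indices are dealt round-robin across
    folds, so per-class counts differ by at most 1; classes with fewer than
    r members are simply spread over as many folds as they have members.
    """
    if r < 2:
        raise ValueError("need at least 2 folds")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(r)]
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(offset + j) % r].append(int(i))
        offset += idx.size  # stagger classes so small classes spread out
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def metrics_report(true_labels, predicted_labels, class_names=None) -> dict:
    """JSON-friendly bundle: per-class P/R/F1, macro averages and kappa."""
    counts = ConfusionCounts.from_labels(true_labels, predicted_labels, class_names)
    table = precision_recall_f1(counts)
    agreement = cohen_kappa(true_labels, predicted_labels)
    return {
        "per_class": {
            str(name): {
                "precision": float(table.loc[name, "precision"]),
                "recall": float(table.loc[name, "recall"]),
                "f1": float(table.loc[name, "f1"]),
            }
            for name in counts.class_names
        },
        "macro": {
            "precision": float(table.loc["macro", "precision"]),
            "recall": float(table.loc["macro", "recall"]),
            "f1": float(table.loc["macro", "f1"]),
        },
        "kappa": agreement.kappa,
        "observed_agreement": agreement.po,
        "chance_agreement": agreement.pe,
        "n_samples": counts.n_samples,
    }
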