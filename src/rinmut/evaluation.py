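"""Binary classification metrics and the 6-fold cross-validation protocol.

Accuracy, precision, recall and F1 are computed from 2x2 contingency
counts; cross-validation is stratified with seeded shuffling, scales node
features with training-split statistics only, trains one classifier per
fold, and reports per-fold metrics plus pooled (micro-averaged) metrics
over the union of held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .features import FeatureTable
from .gat import (
    GATConfig,
    TrainConfig,
    prepare_subgraph,
    predict_nodes,
    train_classifier,
)
from .mutations import LabeledDataset
from .rin import ResidueNetwork

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "precision_recall_f1",
    "majority_ratio",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int = 1
) -> ConfusionCounts:
    """2x2 contingency counts with the stated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / n."""
    if c.n == 0:
        raise ValueError("empty contingency table")
    return (c.tp + c.tn) / c.n


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.

    Undefined 0/0 ratios are reported as 0 by convention.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def majority_ratio(labels: Sequence) -> float:
    """Frequency of the most common class (constant-predictor accuracy floor)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    return counts.max() / len(labels)


def _metrics_dict(c: ConfusionCounts) -> dict:
    precision, recall, f1 = precision_recall_f1(c)
    return {
        "accuracy": accuracy(c),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
        "n": c.n,
    }


def cross_validate(
    dataset: LabeledDataset,
    net: ResidueNetwork,
    features: FeatureTable,
    gat_cfg: GATConfig,
    train_cfg: TrainConfig,
    extractor: Callable,
    k: int = 6,
    seed: int = 0,
    positive_class: int = 1,
) -> dict:
    """Stratified k-fold cross-validation of the subgraph classifier.

    Per fold: feature min--max statistics are fitted on the training
    instances' nodes only and applied to the whole node table, a fresh
    classifier is trained, and the held-out fold is scored.  Headline
    metrics are pooled over all held-out predictions; per-fold metrics are
    reported alongside.  Subgraph extraction is label-independent, so
    extracted subgraphs are shared across folds.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(dataset.labels)
    if len(labels) < k:
        raise ValueError(f"need at least k={k} instances")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    subgraph_cache: dict = {}
    fold_reports = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_sizes = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        if len(np.unique(labels[tr])) < 2:
            raise ValueError(f"fold {fold}: training split has a single class")
        train_rows = features.raw[dataset.node_ids[tr]]
        mins = train_rows.min(axis=0)
        maxs = train_rows.max(axis=0)
        scaled, _ = features.scaled(stats=(mins, maxs))

        sub = LabeledDataset(
            node_ids=dataset.node_ids[tr],
            labels=labels[tr],
            positions=dataset.positions[tr],
            label_scheme=dataset.label_scheme,
            augmentation=(
                None if dataset.augmentation is None else dataset.augmentation[tr]
            ),
        )
        fold_train_cfg = TrainConfig(
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            patience=train_cfg.patience,
            seed=train_cfg.seed + fold,
            class_weighting=train_cfg.class_weighting,
            val_fraction=train_cfg.val_fraction,
        )
        trained = train_classifier(
            gat_cfg, fold_train_cfg, sub, net, scaled, extractor,
            subgraph_cache=subgraph_cache,
        )
        probs = predict_nodes(
            trained, net, scaled, dataset.node_ids[te], extractor,
            aug=None if dataset.augmentation is None else dataset.augmentation[te],
            subgraph_cache=subgraph_cache,
        )
        y_pred = probs.argmax(axis=1)
        c = confusion(labels[te], y_pred, positive_class=positive_class)
        pooled = pooled + c
        fold_sizes.append(len(te))
        fold_reports.append({"fold": fold, **_metrics_dict(c)})

    report = {
        "k": k,
        "seed": seed,
        "fold_sizes": fold_sizes,
        "majority_ratio": majority_ratio(labels),
        "folds": fold_reports,
        "pooled": _metrics_dict(pooled),
        "config": {
            "gat": gat_cfg.__dict__,
            "train": train_cfg.__dict__,
        },
    }
    return report
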