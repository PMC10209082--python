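"""Repeated stratified cross-validation and multiclass performance metrics.

Model selection uses Cohen's kappa (chance-corrected agreement — robust to
the heavy class imbalance of plastid data, where raw accuracy and even
averaged AUC reward predicting only the frequent classes), the average
one-vs-one multiclass AUC of Hand & Till (AU1U), and per-class accuracy
(recall of each true class).  Metrics are computed per CV fold and
repetition, then pooled over all fold x repetition cells.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .base_models import N_TREES_DEFAULT, train_baseline
from .ngram import FeatureMatrix, extract_presence
from .seq_data import LabeledDataset
from .stacking import EnsembleConfig, train_stacked

__all__ = [
    "EvaluationReport",
    "cohen_kappa",
    "au1u",
    "class_accuracy",
    "confusion_from_predictions",
    "repeated_stratified_cv",
    "select_best",
]


def cohen_kappa(confusion) -> float:
    """Cohen's kappa of a k x k confusion matrix (rows = truth).

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    (trace / total) and p_e the agreement expected from the marginals.
    The degenerate case p_e = 1 (all mass in one row and column) is
    defined as 0 with a warning.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (c < 0).any():
        raise ValueError("confusion counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate confusion matrix (chance agreement 1); kappa := 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def au1u(probabilities, truth, classes: Optional[Sequence] = None) -> float:
    """Average one-vs-one multiclass AUC (Hand & Till).

    For every unordered class pair (i, j) present in the truth, the
    rank-based probability that a class-i example scores higher on p(i)
    than a class-j example is averaged with its mirror and the pair values
    are averaged over all pairs.  Ties in scores are credited 0.5; pairs
    with an absent class are skipped.
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth)
    if P.ndim != 2 or P.shape[0] != y.shape[0]:
        raise ValueError("probabilities must be (n, k) aligned with truth")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if classes is None:
        classes = list(range(P.shape[1]))
    classes = list(classes)
    present = [c for c in classes if (y == c).any()]
    if len(present) < 2:
        raise ValueError("AU1U needs at least 2 classes present in the truth")

    def a_hat(i, j):
        """P(score_i of a class-i example > that of a class-j example)."""
        si = P[y == classes[i], i]
        sj = P[y == classes[j], i]
        wins = (si[:, None] > sj[None, :]).sum() + 0.5 * (
            si[:, None] == sj[None, :]
        ).sum()
        return wins / (len(si) * len(sj))

    vals = []
    index = {c: k for k, c in enumerate(classes)}
    for ci, cj in itertools.combinations(present, 2):
        i, j = index[ci], index[cj]
        vals.append(0.5 * (a_hat(i, j) + a_hat(j, i)))
    return float(np.mean(vals))


def class_accuracy(confusion, classes: Optional[Sequence] = None) -> dict:
    """Per-class accuracy = recall of each true class.

    Classes with no true members are reported as None (missing), not 0.
    """
    c = np.asarray(confusion, dtype=float)
    if classes is None:
        classes = list(range(c.shape[0]))
    out = {}
    for i, cls in enumerate(classes):
        total = c[i].sum()
        out[cls] = float(c[i, i] / total) if total > 0 else None
    return out


def confusion_from_predictions(truth, predicted, classes: Sequence) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        mat[idx[t], idx[p]] += 1
    return mat


@dataclass
class EvaluationReport:
    """Per-(repetition, fold) metrics plus pooled aggregates."""

    cells: pd.DataFrame  # columns: rep, fold, kappa, au1u, acc_<class>...
    confusions: list[np.ndarray] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)

    @property
    def mean_kappa(self) -> float:
        return float(self.cells["kappa"].mean())

    @property
    def mean_au1u(self) -> float:
        return float(self.cells["au1u"].mean())

    def mean_class_accuracy(self) -> dict[str, float]:
        return {
            cls: float(self.cells[f"acc_{cls}"].mean())
            for cls in self.classes
            if f"acc_{cls}" in self.cells
        }

    def summary(self) -> dict:
        return {
            "mean_kappa": self.mean_kappa,
            "sd_kappa": float(self.cells["kappa"].std(ddof=1)),
            "mean_au1u": self.mean_au1u,
            "sd_au1u": float(self.cells["au1u"].std(ddof=1)),
            "class_accuracy": self.mean_class_accuracy(),
            "n_cells": int(len(self.cells)),
        }

    def to_json(self) -> str:
        return json.dumps(
            {"summary": self.summary(), "cells": self.cells.to_dict("records")},
            indent=2,
        )


def _stratified_folds(labels: np.ndarray, folds: int, seed: int):
    counts = pd.Series(labels).value_counts()
    rare = counts[counts < folds]
    if len(rare):
        warnings.warn(
            f"classes with fewer members than folds ({list(rare.index)}); "
            "stratification is best-effort"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on the same condition
        return list(skf.split(np.zeros(len(labels)), labels))


def repeated_stratified_cv(
    config: Optional[EnsembleConfig],
    dataset: LabeledDataset,
    folds: int = 5,
    reps: int = 5,
    seed: int = 0,
    msas: Optional[dict] = None,
    features: Optional[FeatureMatrix] = None,
    n_trees: int = N_TREES_DEFAULT,
    model: str = "stacked",
) -> EvaluationReport:
    """Stratified k-fold CV repeated ``reps`` times (fresh folds each time).

    Within each fold iteration the lower-level models and the higher-level
    model are trained on the k-1 training folds only and evaluated on the
    held-out fold, yielding folds x reps metric cells.  ``model="baseline"``
    evaluates the naive multiclass forest instead (``config`` is ignored).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if model not in ("stacked", "baseline"):
        raise ValueError(f"unknown model kind {model!r}")
    labels = np.array([r.fine for r in dataset])
    if any(lab is None for lab in labels):
        raise ValueError("cross-validation requires fully labeled data")
    if features is None:
        features = extract_presence(dataset)
    from .seq_data import FINE_CLASSES

    classes = [c for c in FINE_CLASSES if c in set(labels)]
    rows = []
    confusions = []
    for rep in range(reps):
        fold_seed = (seed + 7919 * rep) % (2**31)
        for fold, (train_idx, test_idx) in enumerate(
            _stratified_folds(labels, folds, fold_seed)
        ):
            train_ds = dataset.subset([dataset.ids[i] for i in train_idx])
            test_ds = dataset.subset([dataset.ids[i] for i in test_idx])
            train_feat = features.rows(train_idx)
            test_feat = features.rows(test_idx)
            if model == "stacked":
                ensemble = train_stacked(
                    config,
                    train_ds,
                    seed=fold_seed + fold,
                    features=train_feat,
                    msas=msas,
                    n_trees=n_trees,
                )
                proba = ensemble.predict_proba(test_ds, test_feat)
                model_classes = ensemble.classes
            else:
                forest, model_classes = train_baseline(
                    train_ds,
                    seed=fold_seed + fold,
                    features=train_feat,
                    n_trees=n_trees,
                )
                X = np.asarray(test_feat.X.todense(), dtype=np.float32)
                proba = forest.predict_proba(X)
            truth = labels[test_idx]
            predicted = [model_classes[i] for i in proba.argmax(axis=1)]
            conf = confusion_from_predictions(truth, predicted, classes)
            confusions.append(conf)
            accs = class_accuracy(conf, classes)
            # AU1U over the evaluated class space
            proba_full = np.zeros((len(truth), len(classes)))
            for j, cls in enumerate(model_classes):
                if cls in classes:
                    proba_full[:, classes.index(cls)] = proba[:, j]
            row_sums = proba_full.sum(axis=1, keepdims=True)
            proba_full = np.divide(
                proba_full, row_sums, out=proba_full, where=row_sums > 0
            )
            cell = {
                "rep": rep,
                "fold": fold,
                "kappa": cohen_kappa(conf),
                "au1u": au1u(proba_full, truth, classes),
            }
            for cls, acc in accs.items():
                cell[f"acc_{cls}"] = acc
            rows.append(cell)
    return EvaluationReport(
        cells=pd.DataFrame(rows), confusions=confusions, classes=classes
    )


def select_best(reports: Sequence[tuple]) -> EnsembleConfig:
    """Pick the configuration with the highest mean CV kappa.

    ``reports`` is a sequence of (EnsembleConfig, EvaluationReport) pairs.
    Exact ties are broken toward fewer lower-level models, then input order.
    """
    if not reports:
        raise ValueError("no reports to select from")
    best = None
    for order, (config, report) in enumerate(reports):
        key = (-report.mean_kappa, len(config.lower), order)
        if best is None or key < best[0]:
            best = (key, config)
    return best[1]
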