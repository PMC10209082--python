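"""Lower-level task models of the localization ensemble.

Each lower-level model answers one labelling question about a protein —
e.g. "is it nuclear-encoded?", "is it a membrane protein?", "does its
N-terminus look like a Tat signal?".  Random-forest models work on
QuiPT-selected gapped n-gram presence features (forests of 500 trees,
sqrt(p) features per split, no tuning); signal models are profile HMMs
built from Sec/Tat alignments.  A naive multiclass forest over all eight
classes serves as the baseline the stacked ensemble is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import profile_hmm as phmm
from .ngram import FeatureMatrix, NGramPattern, extract_presence, select_features
from .seq_data import FINE_CLASSES, LabeledDataset

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "default_registry",
    "smote_oversample",
    "train_model",
    "train_baseline",
    "count_motif_matching_features",
]

NUCLEAR_CLASSES = frozenset({"N_E", "N_TM", "N_S", "N_TL_SEC", "N_TL_TAT"})
PLASTID_CLASSES = frozenset({"P_IM", "P_TM", "P_S"})
MEMBRANE_CLASSES = frozenset({"N_E", "N_TM", "P_IM", "P_TM"})

N_TREES_DEFAULT = 500


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one lower-level model.

    ``negative`` is a frozenset of fine classes or the string ``"rest"``
    (every class not in ``positive``).  HMM models reference the input
    alignment by ``msa_key`` ("Sec" or "Tat") instead of using features.
    """

    name: str
    positive: frozenset
    negative: object = "rest"  # frozenset or "rest"
    algorithm: str = "random_forest"
    smote: bool = False
    feature_alpha: float = 0.01
    msa_key: Optional[str] = None

    def __post_init__(self):
        if self.algorithm not in ("random_forest", "profile_hmm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.negative != "rest":
            if self.positive & self.negative:
                raise ValueError("positive and negative class sets overlap")
        if self.algorithm == "profile_hmm" and self.msa_key is None:
            raise ValueError("profile_hmm models must reference an MSA")

    def negative_classes(self) -> frozenset:
        if self.negative == "rest":
            return frozenset(FINE_CLASSES) - self.positive
        return self.negative

    def task_classes(self) -> frozenset:
        return self.positive | self.negative_classes()


def default_registry() -> list[ModelSpec]:
    """The eight default lower-level models.

    Six n-gram forests handle origin, membrane association and the pairwise
    problems among nuclear-encoded classes, and two profile HMMs detect the
    Sec and Tat lumenal targeting signals.
    """
    return [
        ModelSpec("Nuclear", NUCLEAR_CLASSES),
        ModelSpec("Membrane", MEMBRANE_CLASSES, smote=True),
        ModelSpec("Plastid_membrane", frozenset({"P_IM"}), frozenset({"P_TM"})),
        ModelSpec("N_E_vs_N_TM", frozenset({"N_E"}), frozenset({"N_TM"})),
        ModelSpec(
            "N_S_vs_other_nuclear",
            frozenset({"N_S"}),
            NUCLEAR_CLASSES - {"N_S"},
        ),
        ModelSpec(
            "Nuclear_membrane",
            frozenset({"N_E", "N_TM"}),
            NUCLEAR_CLASSES - {"N_E", "N_TM"},
        ),
        ModelSpec(
            "Sec",
            frozenset({"N_TL_SEC"}),
            algorithm="profile_hmm",
            msa_key="Sec",
        ),
        ModelSpec(
            "Tat",
            frozenset({"N_TL_TAT"}),
            algorithm="profile_hmm",
            msa_key="Tat",
        ),
    ]


def smote_oversample(
    X, y, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary problem by synthesising minority rows (SMOTE).

    A synthetic row interpolates a random minority row toward one of its
    ``k`` nearest minority neighbours (Hamming distance on the binary
    features) and rounds at 0.5 (ties round to 1), so the feature space
    stays binary.  Majority rows are never altered.
    """
    X = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects a binary target")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError(
            "minority class has a single member; disable SMOTE for this task"
        )
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y
    rng = np.random.default_rng(seed)
    minority_rows = X[y == minority]
    # pairwise Hamming distances among minority rows
    dist = (minority_rows[:, None, :] != minority_rows[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.iinfo(np.int64).max)
    k_eff = min(k, n_min - 1)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
    synth = np.empty((n_new, X.shape[1]))
    for i in range(n_new):
        base = int(rng.integers(n_min))
        nb = int(neighbours[base, rng.integers(k_eff)])
        lam = rng.random()
        row = minority_rows[base] + lam * (minority_rows[nb] - minority_rows[base])
        synth[i] = np.floor(row + 0.5)  # ties at 0.5 round up to 1
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


@dataclass
class TrainedModel:
    """A fitted lower-level model (forest or profile HMM)."""

    spec: ModelSpec
    forest: Optional[RandomForestClassifier] = None
    selected_patterns: list[str] = field(default_factory=list)
    importances: Optional[np.ndarray] = None  # Gini, aligned with patterns
    hmm: Optional[phmm.ProfileHMM] = None
    score_mean: float = 0.0
    score_sd: float = 1.0
    hmm_window: int = 100

    def _design(self, features: FeatureMatrix) -> np.ndarray:
        """Dense design matrix in the model's selected-pattern order.

        Patterns unseen in the new data contribute all-zero columns; extra
        patterns in ``features`` are ignored — selection never leaks.
        """
        if not self.selected_patterns:  # empty selection: constant design
            return np.zeros((len(features.ids), 1), dtype=np.float64)
        col = {p: j for j, p in enumerate(features.patterns)}
        out = np.zeros((len(features.ids), len(self.selected_patterns)), dtype=np.float64)
        for jj, pat in enumerate(self.selected_patterns):
            if pat in col:
                out[:, jj] = np.asarray(
                    features.X[:, col[pat]].todense()
                ).ravel()
        return out

    def predict_proba(
        self, dataset: LabeledDataset, features: Optional[FeatureMatrix] = None
    ) -> np.ndarray:
        """(n, 2) probabilities over (negative, positive) for forest models."""
        if self.forest is None:
            raise ValueError("predict_proba is defined for forest models only")
        if features is None:
            features = extract_presence(dataset)
        design = self._design(features)
        proba = self.forest.predict_proba(design)
        pos_idx = list(self.forest.classes_).index(1)
        return np.column_stack([proba[:, 1 - pos_idx], proba[:, pos_idx]])

    def meta_feature(
        self, dataset: LabeledDataset, features: Optional[FeatureMatrix] = None
    ) -> np.ndarray:
        """Per-record meta-feature fed to the higher-level model.

        Positive-class probability for forests; standardized forward
        log-odds (z-scored with the training mean/sd) for HMM models.
        """
        if self.spec.algorithm == "random_forest":
            return self.predict_proba(dataset, features)[:, 1]
        scores = np.array(
            [
                phmm.score_logodds(self.hmm, rec.sequence, window=self.hmm_window)
                for rec in dataset
            ]
        )
        return (scores - self.score_mean) / self.score_sd


def _binary_task(dataset: LabeledDataset, spec: ModelSpec):
    pos, neg = spec.positive, spec.negative_classes()
    idx, y = [], []
    for i, rec in enumerate(dataset):
        if rec.fine in pos:
            idx.append(i)
            y.append(1)
        elif rec.fine in neg:
            idx.append(i)
            y.append(0)
    return np.array(idx, dtype=int), np.array(y, dtype=int)


def train_model(
    spec: ModelSpec,
    dataset: LabeledDataset,
    seed: int,
    features: Optional[FeatureMatrix] = None,
    msas: Optional[dict] = None,
    n_trees: int = N_TREES_DEFAULT,
) -> TrainedModel:
    """Fit one lower-level model on (the relevant subset of) a dataset.

    Forest models: n-gram extraction, QuiPT selection at
    ``spec.feature_alpha``, optional SMOTE balancing, then a probability
    forest.  HMM models: build the profile from ``msas[spec.msa_key]`` and
    record the training-score mean/sd used to standardize meta-features.
    Deterministic for a fixed seed.
    """
    if spec.algorithm == "profile_hmm":
        if not msas or spec.msa_key not in msas:
            raise ValueError(f"model {spec.name!r} needs msas[{spec.msa_key!r}]")
        hmm = phmm.build_from_msa(msas[spec.msa_key])
        model = TrainedModel(spec=spec, hmm=hmm)
        scores = np.array(
            [
                phmm.score_logodds(hmm, rec.sequence, window=model.hmm_window)
                for rec in dataset
            ]
        )
        model.score_mean = float(scores.mean())
        sd = float(scores.std(ddof=0))
        model.score_sd = sd if sd > 0 else 1.0
        return model

    if features is None:
        features = extract_presence(dataset)
    idx, y = _binary_task(dataset, spec)
    if len(np.unique(y)) < 2:
        missing = "positive" if 1 not in y else "negative"
        raise ValueError(
            f"model {spec.name!r}: no {missing} examples in the training data"
        )
    task_features = features.rows(idx)
    selected, _ = select_features(task_features, y, alpha=spec.feature_alpha)
    X = np.asarray(selected.X.todense(), dtype=np.float64)
    if X.shape[1] == 0:
        # degenerate but legal: constant design, the forest predicts the prior
        X = np.zeros((len(y), 1))
        patterns: list[str] = []
    else:
        patterns = list(selected.patterns)
    y_fit = y
    if spec.smote:
        X, y_fit = smote_oversample(X, y, seed=seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y_fit)
    importances = forest.feature_importances_ if patterns else np.zeros(0)
    return TrainedModel(
        spec=spec,
        forest=forest,
        selected_patterns=patterns,
        importances=importances,
    )


def train_baseline(
    dataset: LabeledDataset,
    seed: int,
    features: Optional[FeatureMatrix] = None,
    n_trees: int = N_TREES_DEFAULT,
) -> tuple[RandomForestClassifier, list[str]]:
    """Naive multiclass forest over the full (unselected) presence matrix.

    Returns the fitted forest and its class order.  This is the baseline
    that the stacked ensemble must beat: with heavy class imbalance a
    single multiclass forest recalls frequent classes and fails on rare
    ones.
    """
    labels = [r.fine for r in dataset]
    if any(lab is None for lab in labels):
        raise ValueError("baseline training requires fully labeled data")
    if len(set(labels)) < 2:
        raise ValueError("baseline needs at least 2 classes")
    if features is None:
        features = extract_presence(dataset)
    X = np.asarray(features.X.todense(), dtype=np.float32)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    return forest, list(forest.classes_)


def count_motif_matching_features(
    model: TrainedModel, motif: str, top_k: Optional[int] = None
) -> int:
    """How many of the model's most important n-grams fit inside a motif.

    Patterns are ranked by Gini importance (descending); the top ``top_k``
    (or all, if None) are tested for a full embedding of their match
    positions in the motif string.  Patterns longer than the motif simply
    do not match.
    """
    if model.forest is None or model.importances is None:
        raise ValueError("motif matching requires a trained forest model")
    order = np.argsort(-model.importances, kind="stable")
    if top_k is not None:
        order = order[:top_k]
    count = 0
    for j in order:
        pattern = NGramPattern.from_string(model.selected_patterns[j])
        if pattern.matches(motif):
            count += 1
    return count
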