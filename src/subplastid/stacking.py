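"""Stacked ensemble: lower-level models + a higher-level aggregator.

An ensemble is a pair (S, G) of a set of lower-level models S = {S1..Sn}
and an aggregation function G, with prediction y = G(S1(x), ..., Sn(x));
stacking makes G itself a predictive model (a probability forest or a
multinomial log-linear model) trained on the lower models' outputs.  The
meta-feature of a forest model is its positive-class probability; of an HMM
model, its standardized log-odds score.

Conditional routing implements expert rules of the form "a protein the
Nuclear model calls plastid-encoded is not processed by the nuclear-only
models": a guard model's decision masks a subset of models per record.  A
masked model contributes 0 in its meta-feature cell, with a companion
binary mask column telling the aggregator the cell was masked rather than
genuinely zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .base_models import (
    ModelSpec,
    N_TREES_DEFAULT,
    TrainedModel,
    default_registry,
    train_model,
)
from .ngram import FeatureMatrix, extract_presence, select_features
from .seq_data import FINE_CLASSES, LabeledDataset, map_generalized

__all__ = [
    "RoutingRule",
    "EnsembleConfig",
    "StackedEnsemble",
    "default_config",
    "apply_routing",
    "build_meta_features",
    "train_stacked",
    "enumerate_model_sets",
    "cross_configurations",
    "config_to_json",
    "config_from_json",
]


@dataclass(frozen=True)
class RoutingRule:
    """When ``guard`` decides ``outcome`` (1 = positive side, 0 = negative),
    the models in ``inactive`` are not evaluated for that record."""

    guard: str
    outcome: int
    inactive: tuple[str, ...]


@dataclass
class EnsembleConfig:
    lower: list[ModelSpec] = field(default_factory=default_registry)
    higher: str = "random_forest"  # or "multinomial_log_linear"
    conditional: bool = False
    routing_rules: list[RoutingRule] = field(default_factory=list)
    out_of_fold: bool = False  # higher model trained on out-of-fold meta features

    def __post_init__(self):
        if self.higher not in ("random_forest", "multinomial_log_linear"):
            raise ValueError(f"unknown higher-level model {self.higher!r}")
        names = [spec.name for spec in self.lower]
        if len(set(names)) != len(names):
            raise ValueError("lower-level model names must be unique")
        if self.conditional and not self.routing_rules:
            self.routing_rules = default_routing_rules(self.lower)
        for rule in self.routing_rules:
            if rule.guard not in names:
                raise ValueError(f"routing guard {rule.guard!r} not in lower models")
            unknown = set(rule.inactive) - set(names)
            if unknown:
                raise ValueError(f"routing rule references unknown models {unknown}")
            if rule.guard in rule.inactive:
                raise ValueError("a guard model cannot deactivate itself")
        self._check_acyclic()

    def _check_acyclic(self):
        # guard -> deactivatable models must form a DAG so guards can be
        # evaluated before the models they control
        edges: dict[str, set[str]] = {}
        for rule in self.routing_rules:
            edges.setdefault(rule.guard, set()).update(rule.inactive)
        seen: dict[str, int] = {}

        def visit(node: str):
            state = seen.get(node, 0)
            if state == 1:
                raise ValueError("cyclic guard dependencies in routing rules")
            if state == 2:
                return
            seen[node] = 1
            for nxt in edges.get(node, ()):
                visit(nxt)
            seen[node] = 2

        for node in edges:
            visit(node)

    @property
    def maskable(self) -> list[str]:
        """Models that some routing rule can deactivate (spec order)."""
        inactive = set().union(*(set(r.inactive) for r in self.routing_rules)) \
            if self.routing_rules else set()
        return [s.name for s in self.lower if s.name in inactive]


def default_routing_rules(lower: Sequence[ModelSpec]) -> list[RoutingRule]:
    """Origin-based routing: the Nuclear model gates origin-specific models."""
    names = {s.name for s in lower}
    if "Nuclear" not in names:
        return []
    nuclear_only = tuple(
        n
        for n in (
            "N_E_vs_N_TM",
            "N_S_vs_other_nuclear",
            "Nuclear_membrane",
            "Sec",
            "Tat",
        )
        if n in names
    )
    plastid_only = tuple(n for n in ("Plastid_membrane",) if n in names)
    rules = []
    if nuclear_only:
        rules.append(RoutingRule("Nuclear", 0, nuclear_only))
    if plastid_only:
        rules.append(RoutingRule("Nuclear", 1, plastid_only))
    return rules


def default_config(conditional: bool = False, higher: str = "random_forest") -> EnsembleConfig:
    return EnsembleConfig(conditional=conditional, higher=higher)


def apply_routing(
    rules: Sequence[RoutingRule],
    guard_outputs: dict[str, np.ndarray],
    model_names: Sequence[str],
    n_records: int,
) -> np.ndarray:
    """Boolean activity mask (n_records, n_models) from guard decisions.

    ``guard_outputs`` maps guard names to positive-class probabilities.  A
    guard decides the positive side when p > 0.5 and the negative side when
    p < 0.5; at exactly 0.5 neither rule fires, so ties keep every model
    active.  Without rules the mask is all-true.
    """
    mask = np.ones((n_records, len(model_names)), dtype=bool)
    col = {name: j for j, name in enumerate(model_names)}
    for rule in rules:
        p = np.asarray(guard_outputs[rule.guard])
        fired = (p > 0.5) if rule.outcome == 1 else (p < 0.5)
        for name in rule.inactive:
            mask[fired, col[name]] = False
    return mask


def build_meta_features(
    lower: Sequence[TrainedModel],
    dataset: LabeledDataset,
    features: Optional[FeatureMatrix] = None,
    rules: Sequence[RoutingRule] = (),
    maskable: Sequence[str] = (),
) -> tuple[np.ndarray, list[str]]:
    """Meta-feature matrix: one column per lower model (+ mask columns).

    Masked cells are set to 0 and flagged in the companion ``<name>__masked``
    column, which exists for every model any routing rule can deactivate.
    """
    if features is None:
        features = extract_presence(dataset)
    names = [m.spec.name for m in lower]
    raw = {m.spec.name: m.meta_feature(dataset, features) for m in lower}
    n = len(dataset)
    if rules:
        guard_outputs = {r.guard: raw[r.guard] for r in rules}
        active = apply_routing(rules, guard_outputs, names, n)
    else:
        active = np.ones((n, len(names)), dtype=bool)
    cols = [np.where(active[:, j], raw[name], 0.0) for j, name in enumerate(names)]
    col_names = list(names)
    for name in maskable:
        j = names.index(name)
        cols.append((~active[:, j]).astype(float))
        col_names.append(f"{name}__masked")
    return np.column_stack(cols), col_names


def _make_higher(kind: str, seed: int, n_trees: int):
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
    # multinomial log-linear by penalized maximum likelihood; the tiny ridge
    # only guards against perfect separation
    return LogisticRegression(C=1e6, max_iter=2000, random_state=seed)


@dataclass
class StackedEnsemble:
    config: EnsembleConfig
    lower: list[TrainedModel]
    higher: object
    classes: list[str]
    meta_columns: list[str]
    envelope_forest: Optional[RandomForestClassifier] = None
    envelope_patterns: list[str] = field(default_factory=list)

    def _meta(self, dataset: LabeledDataset, features: Optional[FeatureMatrix]):
        rules = self.config.routing_rules if self.config.conditional else ()
        meta, _ = build_meta_features(
            self.lower, dataset, features, rules, self.config.maskable
        )
        return meta

    def predict_proba(
        self, dataset: LabeledDataset, features: Optional[FeatureMatrix] = None
    ) -> np.ndarray:
        """(n, k) class probabilities, columns ordered as ``self.classes``."""
        if features is None:
            features = extract_presence(dataset)
        meta = self._meta(dataset, features)
        proba = self.higher.predict_proba(meta)
        order = [list(self.higher.classes_).index(c) for c in self.classes]
        return proba[:, order]

    def _envelope_side(
        self, dataset: LabeledDataset, features: FeatureMatrix
    ) -> tuple[list[str], np.ndarray]:
        if self.envelope_patterns:
            col = {p: j for j, p in enumerate(features.patterns)}
            X = np.zeros((len(dataset), len(self.envelope_patterns)))
            for jj, pat in enumerate(self.envelope_patterns):
                if pat in col:
                    X[:, jj] = np.asarray(features.X[:, col[pat]].todense()).ravel()
        else:  # empty selection: the constant design used in training
            X = np.zeros((len(dataset), 1))
        proba = self.envelope_forest.predict_proba(X)
        classes = list(self.envelope_forest.classes_)
        best = proba.argmax(axis=1)
        return [classes[i] for i in best], proba.max(axis=1)

    def predict(
        self, dataset: LabeledDataset, features: Optional[FeatureMatrix] = None
    ) -> pd.DataFrame:
        """Per-record report: fine class, probabilities, derived taxonomy.

        Argmax ties are broken by the fixed class order of ``self.classes``.
        Predicted thylakoid-lumen proteins get their import pathway; if the
        envelope submodel is attached, proteins predicted N_E also receive
        an inner/outer membrane (IM/OM) call.
        """
        if features is None:
            features = extract_presence(dataset)
        proba = self.predict_proba(dataset, features)
        best = proba.argmax(axis=1)  # first max wins: fixed class order
        rows = []
        side_calls, side_probs = (None, None)
        if self.envelope_forest is not None:
            side_calls, side_probs = self._envelope_side(dataset, features)
        for i, rec in enumerate(dataset):
            fine = self.classes[best[i]]
            origin, generalized = map_generalized(fine)
            pathway = {"N_TL_SEC": "Sec", "N_TL_TAT": "Tat"}.get(fine)
            row = {
                "id": rec.id,
                "fine_class": fine,
                "probability": float(proba[i, best[i]]),
                "origin": origin,
                "localization": generalized,
                "pathway": pathway,
                "envelope_side": None,
                "envelope_side_probability": None,
            }
            if fine == "N_E" and side_calls is not None:
                row["envelope_side"] = side_calls[i]
                row["envelope_side_probability"] = float(side_probs[i])
            for j, cls in enumerate(self.classes):
                row[f"p_{cls}"] = float(proba[i, j])
            rows.append(row)
        return pd.DataFrame(rows)


def _train_lower(
    config: EnsembleConfig,
    dataset: LabeledDataset,
    seed: int,
    features: FeatureMatrix,
    msas: Optional[dict],
    n_trees: int,
) -> list[TrainedModel]:
    return [
        train_model(
            spec,
            dataset,
            seed=(seed + 1009 * i) % (2**31),
            features=features,
            msas=msas,
            n_trees=n_trees,
        )
        for i, spec in enumerate(config.lower)
    ]


def _train_envelope_submodel(
    dataset: LabeledDataset,
    seed: int,
    features: FeatureMatrix,
    n_trees: int,
):
    idx = [
        i
        for i, rec in enumerate(dataset)
        if rec.fine == "N_E" and rec.label.envelope_side is not None
    ]
    sides = [dataset[i].label.envelope_side for i in idx]
    if len(set(sides)) < 2 or min(sides.count("IM"), sides.count("OM")) < 2:
        return None, []
    sub = features.rows(idx)
    y = np.array([1 if s == "IM" else 0 for s in sides])
    selected, _ = select_features(sub, y, alpha=0.01)
    X = np.asarray(selected.X.todense(), dtype=np.float64)
    patterns = list(selected.patterns)
    if X.shape[1] == 0:
        X, patterns = np.zeros((len(y), 1)), []
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X, ["IM" if v == 1 else "OM" for v in y])
    return forest, patterns


def train_stacked(
    config: EnsembleConfig,
    dataset: LabeledDataset,
    seed: int,
    features: Optional[FeatureMatrix] = None,
    msas: Optional[dict] = None,
    n_trees: int = N_TREES_DEFAULT,
    envelope_submodel: bool = False,
) -> StackedEnsemble:
    """Train the full stacked ensemble on a labeled dataset.

    Lower-level models are trained on the full training data and, by
    default, the higher-level model is trained on their in-sample outputs
    for those same records; ``config.out_of_fold=True`` switches the
    higher-level training signal to out-of-fold lower-model predictions for
    users worried about stacking leakage.  Classes absent from the data are
    dropped from the output space with a warning.
    """
    labels = [r.fine for r in dataset]
    if any(lab is None for lab in labels):
        raise ValueError("training requires fully labeled data")
    present = [c for c in FINE_CLASSES if c in set(labels)]
    if len(present) < len(FINE_CLASSES):
        warnings.warn(
            f"classes absent from training data dropped from output space: "
            f"{sorted(set(FINE_CLASSES) - set(present))}"
        )
    if features is None:
        features = extract_presence(dataset)
    lower = _train_lower(config, dataset, seed, features, msas, n_trees)
    rules = config.routing_rules if config.conditional else ()
    meta_columns = [s.name for s in config.lower] + [
        f"{name}__masked" for name in config.maskable
    ]
    if config.out_of_fold:
        meta = _out_of_fold_meta(config, dataset, seed, features, msas, n_trees)
    else:
        meta, meta_columns = build_meta_features(
            lower, dataset, features, rules, config.maskable
        )
    higher = _make_higher(config.higher, seed, n_trees)
    higher.fit(meta, labels)
    env_forest, env_patterns = (None, [])
    if envelope_submodel:
        env_forest, env_patterns = _train_envelope_submodel(
            dataset, seed, features, n_trees
        )
    return StackedEnsemble(
        config=config,
        lower=lower,
        higher=higher,
        classes=present,
        meta_columns=meta_columns,
        envelope_forest=env_forest,
        envelope_patterns=env_patterns,
    )


def _out_of_fold_meta(config, dataset, seed, features, msas, n_trees):
    from sklearn.model_selection import StratifiedKFold

    labels = np.array([r.fine for r in dataset])
    n = len(dataset)
    rules = config.routing_rules if config.conditional else ()
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % (2**31))
    meta = None
    for train_idx, test_idx in skf.split(np.zeros(n), labels):
        sub = dataset.subset([dataset.ids[i] for i in train_idx])
        sub_features = features.rows(train_idx)
        lower = _train_lower(config, sub, seed, sub_features, msas, n_trees)
        test_ds = dataset.subset([dataset.ids[i] for i in test_idx])
        fold_meta, _ = build_meta_features(
            lower, test_ds, features.rows(test_idx), rules, config.maskable
        )
        if meta is None:
            meta = np.zeros((n, fold_meta.shape[1]))
        meta[test_idx] = fold_meta
    return meta


# -- config (de)serialization ----------------------------------------------


def config_to_json(config: EnsembleConfig) -> str:
    import json

    def spec_dict(spec: ModelSpec) -> dict:
        return {
            "name": spec.name,
            "positive": sorted(spec.positive),
            "negative": "rest"
            if spec.negative == "rest"
            else sorted(spec.negative),
            "algorithm": spec.algorithm,
            "smote": spec.smote,
            "feature_alpha": spec.feature_alpha,
            "msa_key": spec.msa_key,
        }

    return json.dumps(
        {
            "schema_version": 1,
            "lower": [spec_dict(s) for s in config.lower],
            "higher": config.higher,
            "conditional": config.conditional,
            "routing_rules": [
                {"guard": r.guard, "outcome": r.outcome, "inactive": list(r.inactive)}
                for r in config.routing_rules
            ],
            "out_of_fold": config.out_of_fold,
        },
        indent=2,
    )


def config_from_json(text: str) -> EnsembleConfig:
    import json

    data = json.loads(text)
    lower = [
        ModelSpec(
            name=d["name"],
            positive=frozenset(d["positive"]),
            negative="rest" if d["negative"] == "rest" else frozenset(d["negative"]),
            algorithm=d.get("algorithm", "random_forest"),
            smote=d.get("smote", False),
            feature_alpha=d.get("feature_alpha", 0.01),
            msa_key=d.get("msa_key"),
        )
        for d in data["lower"]
    ]
    rules = [
        RoutingRule(r["guard"], r["outcome"], tuple(r["inactive"]))
        for r in data.get("routing_rules", [])
    ]
    return EnsembleConfig(
        lower=lower,
        higher=data.get("higher", "random_forest"),
        conditional=data.get("conditional", False),
        routing_rules=rules,
        out_of_fold=data.get("out_of_fold", False),
    )


# -- configuration-space enumeration ---------------------------------------


def enumerate_model_sets(grammar: Sequence[Sequence[Iterable[str]]]) -> list[frozenset]:
    """Enumerate lower-level model sets from a slot grammar.

    ``grammar`` is a list of slots; each slot is a list of options; each
    option is an iterable of model names (possibly empty, for "none").  The
    result is the Cartesian product of one option per slot, as deduplicated
    frozensets of model names in first-occurrence order.
    """
    slots = [list(slot) for slot in grammar]
    if any(len(slot) == 0 for slot in slots):
        raise ValueError("every grammar slot needs at least one option")
    seen: dict[frozenset, None] = {}
    for combo in itertools.product(*slots):
        names = frozenset(itertools.chain.from_iterable(combo))
        seen.setdefault(names)
    return list(seen)


def cross_configurations(
    model_sets: Sequence,
    ensemble_types: Sequence[str] = ("plain", "conditional"),
    higher_types: Sequence[str] = ("random_forest", "multinomial_log_linear"),
) -> list[tuple]:
    """Cross model sets with ensemble type and higher-level model type.

    Every model set yields len(ensemble_types) x len(higher_types)
    configurations (4 with the defaults).
    """
    return [
        (ms, et, ht)
        for ms in model_sets
        for et in ensemble_types
        for ht in higher_types
    ]
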