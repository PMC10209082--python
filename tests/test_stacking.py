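import numpy as np
import pytest

from subplastid.base_models import default_registry, train_model
from subplastid.stacking import (
    EnsembleConfig,
    RoutingRule,
    apply_routing,
    build_meta_features,
    config_from_json,
    config_to_json,
    cross_configurations,
    default_config,
    enumerate_model_sets,
    train_stacked,
)

MODEL_NAMES = [s.name for s in default_registry()]


@pytest.fixture(scope="module")
def trained_ensemble(request):
    small_dataset = request.getfixturevalue("small_dataset")
    small_features = request.getfixturevalue("small_features")
    signal_msas = request.getfixturevalue("signal_msas")
    return train_stacked(
        default_config(),
        small_dataset,
        seed=3,
        features=small_features,
        msas=signal_msas,
        n_trees=100,
        envelope_submodel=True,
    )


class TestConfigValidation:
    def test_unknown_guard_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(
                routing_rules=[RoutingRule("NoSuchModel", 0, ("Sec",))]
            )

    def test_self_guard_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(
                routing_rules=[RoutingRule("Nuclear", 0, ("Nuclear",))]
            )

    def test_cyclic_guards_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            EnsembleConfig(
                routing_rules=[
                    RoutingRule("Nuclear", 0, ("Membrane",)),
                    RoutingRule("Membrane", 0, ("Nuclear",)),
                ]
            )

    def test_conditional_gets_default_rules(self):
        config = default_config(conditional=True)
        assert config.routing_rules
        assert {r.guard for r in config.routing_rules} == {"Nuclear"}

    def test_json_round_trip(self):
        config = default_config(conditional=True, higher="multinomial_log_linear")
        back = config_from_json(config_to_json(config))
        assert [s.name for s in back.lower] == [s.name for s in config.lower]
        assert back.higher == config.higher
        assert back.routing_rules == config.routing_rules


class TestRouting:
    def test_no_rules_all_active(self):
        mask = apply_routing([], {}, MODEL_NAMES, 4)
        assert mask.all()

    def test_guard_decision_masks_models(self):
        rules = [RoutingRule("Nuclear", 0, ("Sec", "Tat"))]
        guard = {"Nuclear": np.array([0.9, 0.1])}
        mask = apply_routing(rules, guard, MODEL_NAMES, 2)
        sec, tat = MODEL_NAMES.index("Sec"), MODEL_NAMES.index("Tat")
        assert mask[0, sec] and mask[0, tat]  # predicted nuclear: active
        assert not mask[1, sec] and not mask[1, tat]  # predicted plastid

    def test_tie_at_half_keeps_models_active(self):
        rules = [
            RoutingRule("Nuclear", 0, ("Sec",)),
            RoutingRule("Nuclear", 1, ("Plastid_membrane",)),
        ]
        guard = {"Nuclear": np.array([0.5])}
        mask = apply_routing(rules, guard, MODEL_NAMES, 1)
        assert mask.all()


class TestMetaFeatures:
    def test_unconditional_has_one_column_per_model(
        self, small_dataset, small_features, signal_msas
    ):
        lower = [
            train_model(
                spec, small_dataset, seed=1, features=small_features,
                msas=signal_msas, n_trees=20,
            )
            for spec in default_registry()
        ]
        meta, names = build_meta_features(lower, small_dataset, small_features)
        assert meta.shape == (len(small_dataset), 8)
        assert names == MODEL_NAMES

    def test_conditional_adds_mask_columns_and_zeroes_cells(
        self, small_dataset, small_features, signal_msas
    ):
        config = default_config(conditional=True)
        lower = [
            train_model(
                spec, small_dataset, seed=1, features=small_features,
                msas=signal_msas, n_trees=20,
            )
            for spec in config.lower
        ]
        meta, names = build_meta_features(
            lower,
            small_dataset,
            small_features,
            config.routing_rules,
            config.maskable,
        )
        n_maskable = len(config.maskable)
        assert meta.shape[1] == 8 + n_maskable
        # wherever a mask column is 1, the corresponding model cell is 0
        for name in config.maskable:
            cell = meta[:, names.index(name)]
            flag = meta[:, names.index(f"{name}__masked")]
            assert np.all(cell[flag == 1] == 0)
        assert flag.sum() > 0  # plastid records do get guarded out


class TestTrainStacked:
    def test_probabilities_over_eight_classes(
        self, trained_ensemble, small_dataset, small_features
    ):
        proba = trained_ensemble.predict_proba(small_dataset, small_features)
        assert proba.shape == (len(small_dataset), 8)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_end_to_end_determinism(
        self, small_dataset, small_features, signal_msas
    ):
        kwargs = dict(
            features=small_features, msas=signal_msas, n_trees=50
        )
        a = train_stacked(default_config(), small_dataset, seed=9, **kwargs)
        b = train_stacked(default_config(), small_dataset, seed=9, **kwargs)
        assert np.array_equal(
            a.predict_proba(small_dataset, small_features),
            b.predict_proba(small_dataset, small_features),
        )

    def test_report_taxonomy_fields(
        self, trained_ensemble, small_dataset, small_features
    ):
        report = trained_ensemble.predict(small_dataset, small_features)
        ptm = report[report.fine_class == "P_TM"]
        assert (ptm.origin == "plastid").all()
        assert (ptm.localization == "thylakoid_membrane").all()
        assert ptm.pathway.isna().all()
        assert ptm.envelope_side.isna().all()
        lumen = report[report.fine_class.isin(["N_TL_SEC", "N_TL_TAT"])]
        if len(lumen):
            assert set(lumen.pathway) <= {"Sec", "Tat"}

    def test_envelope_submodel_called_for_n_e(
        self, trained_ensemble, small_dataset, small_features
    ):
        report = trained_ensemble.predict(small_dataset, small_features)
        n_e = report[report.fine_class == "N_E"]
        assert len(n_e) > 0
        assert set(n_e.envelope_side) <= {"IM", "OM"}

    def test_multinomial_higher_level_model(
        self, small_dataset, small_features, signal_msas
    ):
        ensemble = train_stacked(
            default_config(higher="multinomial_log_linear"),
            small_dataset,
            seed=4,
            features=small_features,
            msas=signal_msas,
            n_trees=30,
        )
        proba = ensemble.predict_proba(small_dataset, small_features)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_conditional_ensemble_trains_and_predicts(
        self, small_dataset, small_features, signal_msas
    ):
        ensemble = train_stacked(
            default_config(conditional=True),
            small_dataset,
            seed=5,
            features=small_features,
            msas=signal_msas,
            n_trees=30,
        )
        report = ensemble.predict(small_dataset, small_features)
        assert len(report) == len(small_dataset)


class TestEnumeration:
    def test_signal_slot_choices(self):
        slot = [("Sec",), ("Tat",), ("Sec", "Tat")]
        assert len(enumerate_model_sets([slot])) == 3

    def test_optional_slot_choices(self):
        slot = [(), ("N_TL",), ("TL",)]
        assert len(enumerate_model_sets([slot])) == 3

    def test_product_and_dedup(self):
        grammar = [
            [("base",)],
            [("Sec",), ("Tat",), ("Sec", "Tat")],
            [(), ("extra",)],
        ]
        sets = enumerate_model_sets(grammar)
        assert len(sets) == 6
        assert all("base" in s for s in sets)

    def test_crossing_multiplies_by_four(self):
        sets = enumerate_model_sets([[("a",), ("b",), ("a", "b")]])
        crossed = cross_configurations(sets)
        assert len(crossed) == len(sets) * 4

    def test_empty_slot_rejected(self):
        with pytest.raises(ValueError):
            enumerate_model_sets([[]])
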