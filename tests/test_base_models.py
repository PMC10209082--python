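import numpy as np
import pytest

from subplastid.base_models import (
    ModelSpec,
    count_motif_matching_features,
    default_registry,
    smote_oversample,
    train_baseline,
    train_model,
)
from subplastid.ngram import extract_presence
from subplastid.seq_data import FINE_CLASSES, LabeledDataset


class TestDefaultRegistry:
    def test_eight_models(self):
        assert len(default_registry()) == 8

    def test_nuclear_model_task(self):
        nuclear = next(s for s in default_registry() if s.name == "Nuclear")
        assert nuclear.positive == frozenset(
            {"N_E", "N_TM", "N_S", "N_TL_SEC", "N_TL_TAT"}
        )
        assert nuclear.negative_classes() == frozenset({"P_IM", "P_TM", "P_S"})

    def test_signal_models_are_hmms(self):
        by_name = {s.name: s for s in default_registry()}
        assert by_name["Sec"].algorithm == "profile_hmm"
        assert by_name["Tat"].algorithm == "profile_hmm"
        assert by_name["Sec"].msa_key == "Sec"

    def test_overlapping_task_sides_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", frozenset({"N_S"}), frozenset({"N_S", "P_S"}))

    def test_hmm_spec_requires_msa_reference(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", frozenset({"N_TL_SEC"}), algorithm="profile_hmm")


class TestSmote:
    def test_balances_and_keeps_majority_untouched(self, rng):
        X = rng.integers(0, 2, (15, 6)).astype(float)
        y = np.array([0] * 10 + [1] * 5)
        X_out, y_out = smote_oversample(X, y, seed=3)
        assert (y_out == 0).sum() == (y_out == 1).sum() == 10
        assert np.array_equal(X_out[:15], X)  # originals first, unchanged
        assert set(np.unique(X_out)) <= {0.0, 1.0}

    def test_identical_minority_rows_give_identical_synthetics(self):
        row = np.array([1, 0, 1, 1, 0, 0], dtype=float)
        X = np.vstack([np.zeros((6, 6)), row, row])
        y = np.array([0] * 6 + [1] * 2)
        X_out, _ = smote_oversample(X, y, seed=1)
        for synth in X_out[8:]:
            assert np.array_equal(synth, row)

    def test_seed_determinism(self, rng):
        X = rng.integers(0, 2, (12, 5)).astype(float)
        y = np.array([0] * 8 + [1] * 4)
        a = smote_oversample(X, y, seed=7)
        b = smote_oversample(X, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_singleton_minority_rejected(self):
        X = np.zeros((5, 3))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            smote_oversample(X, y)

    def test_synthetics_stay_near_real_minority_rows(self, rng):
        X = rng.integers(0, 2, (20, 8)).astype(float)
        y = np.array([0] * 14 + [1] * 6)
        X_out, y_out = smote_oversample(X, y, k=3, seed=5)
        minority = X[y == 1]
        dist = (minority[:, None, :] != minority[None, :, :]).sum(axis=2)
        np.fill_diagonal(dist, 0)
        max_nb = dist.max()
        for synth in X_out[20:]:
            nearest = (minority != synth).sum(axis=1).min()
            assert nearest <= max_nb


class TestTrainModel:
    def test_separable_task_fits_perfectly(self, small_dataset, small_features):
        spec = next(s for s in default_registry() if s.name == "Nuclear")
        model = train_model(
            spec, small_dataset, seed=1, features=small_features, n_trees=100
        )
        proba = model.predict_proba(small_dataset, small_features)
        assert np.allclose(proba.sum(axis=1), 1.0)
        truth = np.array(
            [1 if r.fine.startswith("N") else 0 for r in small_dataset]
        )
        assert ((proba[:, 1] > 0.5).astype(int) == truth).mean() == 1.0

    def test_seeded_determinism(self, small_dataset, small_features):
        spec = default_registry()[1]
        a = train_model(spec, small_dataset, 5, features=small_features, n_trees=50)
        b = train_model(spec, small_dataset, 5, features=small_features, n_trees=50)
        assert np.array_equal(
            a.predict_proba(small_dataset, small_features),
            b.predict_proba(small_dataset, small_features),
        )

    def test_one_sided_task_error_names_missing_side(self, small_dataset):
        nuclear_only = LabeledDataset(
            [r for r in small_dataset if r.fine.startswith("N")]
        )
        spec = next(s for s in default_registry() if s.name == "Nuclear")
        with pytest.raises(ValueError, match="negative"):
            train_model(spec, nuclear_only, seed=1, n_trees=10)

    def test_hmm_model_standardizes_training_scores(
        self, small_dataset, small_features, signal_msas
    ):
        spec = next(s for s in default_registry() if s.name == "Tat")
        model = train_model(spec, small_dataset, seed=1, msas=signal_msas)
        z = model.meta_feature(small_dataset, small_features)
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_selection_never_leaks_into_scoring(self, small_dataset, small_features):
        """Scoring records whose observed patterns were absent from the
        training selection yields zero columns, never an error."""
        spec = next(s for s in default_registry() if s.name == "Nuclear")
        model = train_model(
            spec, small_dataset, seed=1, features=small_features, n_trees=20
        )
        from subplastid.seq_data import ProteinRecord

        odd = LabeledDataset([ProteinRecord("odd", "WWWWWWWWWWHHHHHWWWWW")])
        proba = model.predict_proba(odd)
        assert proba.shape == (1, 2) and np.allclose(proba.sum(axis=1), 1.0)


class TestBaseline:
    def test_eight_class_probabilities(self, small_dataset, small_features):
        forest, classes = train_baseline(
            small_dataset, seed=2, features=small_features, n_trees=50
        )
        X = np.asarray(small_features.X.todense(), dtype=np.float32)
        proba = forest.predict_proba(X)
        assert proba.shape == (len(small_dataset), 8)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(classes) == set(FINE_CLASSES)

    def test_single_class_rejected(self, small_dataset):
        one_class = LabeledDataset([r for r in small_dataset if r.fine == "N_S"])
        with pytest.raises(ValueError):
            train_baseline(one_class, seed=1, n_trees=10)


@pytest.fixture(scope="module")
def nuclear_membrane_model():
    from subplastid.synthetic import GeneratorConfig, generate_dataset

    ds = generate_dataset(GeneratorConfig(n_per_class=10, seed=42))
    spec = next(s for s in default_registry() if s.name == "Nuclear_membrane")
    return train_model(spec, ds, seed=1, n_trees=100)


class TestMotifMatching:
    def test_dplg_motif_capture(self, nuclear_membrane_model):
        """The thylakoid-membrane generator embeds the LHCP DPLG motif; the
        trained model's informative n-grams must include DPLG-compatible
        patterns."""
        count_all = count_motif_matching_features(nuclear_membrane_model, "DPLG")
        assert count_all >= 1
        top = count_motif_matching_features(
            nuclear_membrane_model, "DPLG", top_k=50
        )
        assert 0 <= top <= count_all

    def test_counts_monotone_in_top_k(self, nuclear_membrane_model):
        counts = [
            count_motif_matching_features(nuclear_membrane_model, "DPLG", top_k=k)
            for k in (10, 50, 200, None)
        ]
        assert counts == sorted(counts)
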