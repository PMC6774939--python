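import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from freqbias.rf import (
    MODELS,
    ChoiceReference,
    build_choice_reference,
    classify,
    model_choice,
    posterior_probability,
    train_forest,
    variable_importance,
)
from freqbias.simulate import SimulationParams

N_BASE = 6


def fabricated_reference(
    n_per_class=60, *, separation=6.0, seed=0, constant_col=False
) -> ChoiceReference:
    """Three Gaussian classes in a small base-statistics space."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, model in enumerate(MODELS):
        centre = np.zeros(N_BASE)
        centre[i % N_BASE] = separation * (i + 1)
        blocks.append(rng.normal(centre, 1.0, size=(n_per_class, N_BASE)))
        labels.append(np.full(n_per_class, model, dtype=object))
    stats = np.vstack(blocks)
    if constant_col:
        stats[:, -1] = 3.14
    labels = np.concatenate(labels)
    lda = LinearDiscriminantAnalysis(n_components=2)
    axes = lda.fit_transform(stats, labels.astype(str))
    names = [f"s{i}" for i in range(N_BASE)] + ["LD1", "LD2"]
    return ChoiceReference(np.hstack([stats, axes]), labels, names, lda)


class TestTrainForest:
    def test_tree_count_and_votes_sum(self):
        ref = fabricated_reference()
        forest = train_forest(ref, n_trees=37, seed=1)
        assert forest.n_trees == 37
        votes, _ = classify(forest, ref.stats[0])
        assert sum(votes.values()) == 37

    def test_separable_classes_near_zero_oob(self):
        forest = train_forest(fabricated_reference(separation=8.0), 100, seed=2)
        assert forest.oob_error < 0.05

    def test_single_class_errors(self):
        ref = fabricated_reference()
        mono = ChoiceReference(
            ref.stats[:50], np.full(50, "conformity", dtype=object),
            ref.feature_names, ref.lda,
        )
        with pytest.raises(ValueError, match="2 model classes"):
            train_forest(mono, 10)

    def test_oob_error_in_unit_interval(self):
        forest = train_forest(fabricated_reference(separation=0.1, seed=5), 60, seed=3)
        assert 0.0 <= forest.oob_error <= 1.0


class TestClassify:
    def test_training_row_recovers_its_class(self):
        ref = fabricated_reference(separation=8.0)
        forest = train_forest(ref, 100, seed=4)
        votes, selected = classify(forest, ref.stats[0])
        assert selected == ref.labels[0]
        assert votes[selected] > 90

    def test_base_vector_is_projected(self):
        ref = fabricated_reference(separation=8.0)
        forest = train_forest(ref, 50, seed=4)
        base = ref.stats[10, :N_BASE]
        _, from_base = classify(forest, base)
        _, from_full = classify(forest, ref.stats[10])
        assert from_base == from_full

    def test_dimension_mismatch_errors(self):
        forest = train_forest(fabricated_reference(), 10, seed=0)
        with pytest.raises(ValueError, match="statistics"):
            classify(forest, np.zeros(3))

    def test_deterministic_given_forest(self):
        ref = fabricated_reference()
        forest = train_forest(ref, 30, seed=6)
        assert classify(forest, ref.stats[5]) == classify(forest, ref.stats[5])


class TestPosteriorProbability:
    def test_separable_near_one(self):
        ref = fabricated_reference(separation=8.0)
        forest = train_forest(ref, 100, seed=7)
        prob = posterior_probability(forest, ref.stats[0], seed=8)
        assert prob > 0.9

    def test_uninformative_stats_near_chance(self):
        """Labels shuffled against statistics: OOB error ~ 2/3 everywhere, so
        the calibrated posterior probability sits near 1/3."""
        ref = fabricated_reference(n_per_class=80, separation=8.0, seed=9)
        rng = np.random.default_rng(10)
        shuffled = ChoiceReference(
            ref.stats, rng.permutation(ref.labels), ref.feature_names, ref.lda
        )
        forest = train_forest(shuffled, 100, seed=11)
        assert forest.oob_error > 0.5
        # query a held-out point (a training row would be partially memorised
        # by the calibration regression forest)
        centre = np.zeros(N_BASE)
        centre[0] = 8.0
        prob = posterior_probability(forest, rng.normal(centre, 1.0), seed=12)
        assert 0.1 < prob < 0.6


class TestVariableImportance:
    def test_constant_column_zero_importance(self):
        ref = fabricated_reference(constant_col=True)
        forest = train_forest(ref, 80, seed=13)
        imp = variable_importance(forest)
        assert imp[f"s{N_BASE - 1}"] == 0.0
        assert imp.index[0] != f"s{N_BASE - 1}"

    def test_duplicated_column_shares_importance(self):
        """A duplicated statistic splits its importance evenly between the
        two copies, and neither copy dominates the other."""
        ref = fabricated_reference(n_per_class=80, separation=5.0, seed=14)
        forest = train_forest(ref, 150, seed=15)
        base_imp = variable_importance(forest)
        dup = ChoiceReference(
            np.hstack([ref.stats, ref.stats[:, [0]]]),
            ref.labels,
            ref.feature_names + ["s0_copy"],
            ref.lda,
        )
        forest_dup = train_forest(dup, 150, seed=15)
        dup_imp = variable_importance(forest_dup)
        pair = dup_imp["s0"] + dup_imp["s0_copy"]
        # even sharing between the identical copies
        assert abs(dup_imp["s0"] - dup_imp["s0_copy"]) < 0.5 * pair
        # the pair's signal neither vanishes nor explodes relative to the
        # single-column importance
        assert 0.5 * base_imp["s0"] < pair < 3.0 * base_imp["s0"]


class TestBuildChoiceReference:
    BASE = SimulationParams(40, 0.1, 0.0, warmup=15, timesteps=8)

    def test_structure_and_lda_axes(self):
        ref = build_choice_reference(
            4, self.BASE, y_max=6, seed=0, shrinkage=True
        )
        assert len(ref) <= 12
        # 1 + 6 + 8 + 1 base stats + 2 LDA axes
        assert ref.stats.shape[1] == 18
        assert ref.feature_names[-2:] == ["LD1", "LD2"]
        assert set(np.unique(ref.labels)) == set(MODELS)

    def test_reproducible(self):
        a = build_choice_reference(3, self.BASE, y_max=6, seed=5, shrinkage=True)
        b = build_choice_reference(3, self.BASE, y_max=6, seed=5, shrinkage=True)
        assert np.array_equal(a.stats, b.stats)
        assert np.array_equal(a.labels, b.labels)

    def test_model_choice_bundle(self):
        ref = fabricated_reference(separation=8.0)
        forest = train_forest(ref, 60, seed=16)
        res = model_choice(forest, ref.stats[0], seed=17)
        assert sum(res.votes.values()) == 60
        assert res.selected == max(res.votes, key=res.votes.get)
        assert 0.0 <= res.posterior_prob <= 1.0
        assert 0.0 <= res.oob_error <= 1.0
        assert len(res.importances) == len(ref.feature_names)
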