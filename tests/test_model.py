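import numpy as np
import pytest

from shbond.evaluation import roc_auc
from shbond.features import split_dataset
from shbond.model import (
    BoostConfig,
    MemberTrainingError,
    ModelVersionError,
    classify,
    feature_importance,
    load_model,
    member_probabilities,
    predict_proba,
    save_model,
    select_depth,
    train_ensemble,
    undersample,
)
from shbond.synthetic import SignalSpec, make_feature_table


def separable_spec(n=200, seed=0):
    """Residue identity determines the label outright (disjoint supports)."""
    return SignalSpec(
        n_shb=n, n_nhb=n, seed=seed,
        aa_shb={"TYR": 0.5, "ASP": 0.5},
        aa_nhb={"LYS": 0.5, "GLN": 0.5},
        group_shb={"alkyl_hydroxyl": 1.0},
        group_nhb={"alkyl_hydroxyl": 1.0},
    )


class TestUndersample:
    def test_balances_exactly(self):
        data, _ = make_feature_table(SignalSpec(n_shb=101, n_nhb=220, seed=0))
        bal = undersample(data, seed=1)
        assert bal.count("SHB") == bal.count("NHB") == 101

    def test_keeps_every_shb(self):
        data, _ = make_feature_table(SignalSpec(n_shb=40, n_nhb=90, seed=0))
        bal = undersample(data, seed=1)
        shb_rows = [v.as_dict() for v, l in data.rows if l == "SHB"]
        bal_shb = [v.as_dict() for v, l in bal.rows if l == "SHB"]
        assert bal_shb == shb_rows

    def test_already_balanced_unchanged(self):
        data, _ = make_feature_table(SignalSpec(n_shb=5, n_nhb=5, seed=0))
        assert undersample(data, seed=3).rows == data.rows

    def test_seed_changes_subset_not_size(self):
        data, _ = make_feature_table(SignalSpec(n_shb=50, n_nhb=200, seed=0))
        a = undersample(data, seed=1)
        b = undersample(data, seed=2)
        assert len(a) == len(b) == 100
        assert a.to_frame().to_csv() != b.to_frame().to_csv()

    def test_shb_majority_returns_input(self):
        data, _ = make_feature_table(SignalSpec(n_shb=30, n_nhb=10, seed=0))
        assert undersample(data, seed=0).rows == data.rows


class TestDepthSelection:
    def test_degenerate_grid_returns_that_depth(self):
        data, _ = make_feature_table(SignalSpec(n_shb=15, n_nhb=15, seed=0))
        config = BoostConfig(n_trees=10, depth_grid=(4,))
        assert select_depth(data, config, seed=0) == 4

    def test_single_split_signal_selects_shallow_depth(self):
        """A dataset whose optimal rule is one categorical split needs only a
        shallow tree."""
        data, _ = make_feature_table(separable_spec(n=120, seed=4))
        config = BoostConfig(n_trees=40, depth_grid=(1, 2, 4, 8))
        assert select_depth(data, config, seed=0) <= 3

    def test_deterministic_given_seed(self):
        data, _ = make_feature_table(SignalSpec(n_shb=30, n_nhb=30,
                                                strength=0.0, seed=2))
        config = BoostConfig(n_trees=20, depth_grid=(1, 2, 3))
        d1 = select_depth(data, config, seed=5)
        d2 = select_depth(data, config, seed=5)
        assert d1 == d2


class TestTraining:
    def test_separable_data_fit_perfectly(self):
        data, _ = make_feature_table(separable_spec(n=200, seed=0))
        ens = train_ensemble(data, BoostConfig(n_trees=100, depth_grid=(2,),
                                               base_seed=0))
        probs = predict_proba(ens, data)
        pred = np.where(probs >= 0.5, "SHB", "NHB")
        assert (pred == np.array(data.labels())).mean() == 1.0

    def test_single_class_raises(self):
        data, _ = make_feature_table(SignalSpec(n_shb=20, n_nhb=0, seed=0))
        with pytest.raises(ValueError):
            train_ensemble(data, BoostConfig(n_trees=10, depth_grid=(1,)))

    def test_ensemble_has_ten_members(self, tiny_ensemble):
        ens, _ = tiny_ensemble
        assert len(ens.members) == 10
        assert len(ens.depths) == 10

    def test_retraining_is_deterministic(self):
        data, _ = make_feature_table(SignalSpec(n_shb=40, n_nhb=90, seed=6))
        config = BoostConfig(n_trees=30, depth_grid=(2,), base_seed=3)
        p1 = predict_proba(train_ensemble(data, config), data)
        p2 = predict_proba(train_ensemble(data, config), data)
        np.testing.assert_array_equal(p1, p2)


class TestPrediction:
    def test_probability_is_exact_member_mean(self, tiny_ensemble):
        ens, data = tiny_ensemble
        probs = predict_proba(ens, data)
        members = member_probabilities(ens, data)
        assert members.shape[1] == 10
        np.testing.assert_allclose(probs, members.mean(axis=1), rtol=0, atol=0)

    def test_probabilities_in_unit_interval(self, tiny_ensemble):
        ens, data = tiny_ensemble
        probs = predict_proba(ens, data)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_single_vector_prediction(self, tiny_ensemble):
        ens, data = tiny_ensemble
        vec = data.rows[0][0]
        p = predict_proba(ens, vec)
        assert p.shape == (1,)
        assert 0.0 <= p[0] <= 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "prob,threshold,expected",
        [(0.870, 0.870, "SHB"), (0.5, 0.870, "NHB"), (0.0, 0.0, "SHB"),
         (0.93, 0.870, "SHB"), (0.8699, 0.870, "NHB")],
    )
    def test_threshold_boundary(self, prob, threshold, expected):
        assert classify(prob, threshold) == expected

    def test_zero_threshold_all_shb(self):
        probs = np.linspace(0, 1, 11)
        assert all(classify(probs, 0.0) == "SHB")

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            classify(0.5, 1.5)

    def test_raising_threshold_never_adds_positives(self, tiny_ensemble):
        ens, data = tiny_ensemble
        probs = predict_proba(ens, data)
        counts = [np.sum(classify(probs, t) == "SHB")
                  for t in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestImportance:
    def test_scores_sum_to_hundred(self, tiny_ensemble):
        ens, _ = tiny_ensemble
        imp = feature_importance(ens)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)
        assert len(imp) == 14

    def test_planted_residue_signal_ranks_first(self):
        """When only the residue identity separates the classes, it must
        receive the top importance score."""
        spec = SignalSpec(
            n_shb=250, n_nhb=250, seed=8,
            # SER vs THR: same charge, same heteroatom, so no feature other
            # than the residue identity carries the signal
            aa_shb={"SER": 0.9, "THR": 0.1},
            aa_nhb={"SER": 0.1, "THR": 0.9},
            group_shb={"alkyl_hydroxyl": 1.0},
            group_nhb={"alkyl_hydroxyl": 1.0},
        )
        data, _ = make_feature_table(spec)
        ens = train_ensemble(data, BoostConfig(n_trees=100, depth_grid=(2,),
                                               base_seed=0))
        imp = feature_importance(ens)
        assert max(imp, key=imp.get) == "aa_residue"

    def test_pure_noise_importances_spread_out(self):
        data, _ = make_feature_table(SignalSpec(n_shb=150, n_nhb=150,
                                                strength=0.0, seed=9))
        ens = train_ensemble(data, BoostConfig(n_trees=60, depth_grid=(2,),
                                               base_seed=0))
        imp = feature_importance(ens)
        assert max(imp.values()) < 60.0  # nothing dominates without signal


class TestPersistence:
    def test_roundtrip_preserves_predictions(self, tiny_ensemble, tmp_path):
        ens, data = tiny_ensemble
        path = tmp_path / "model.joblib"
        save_model(ens, path)
        back = load_model(path)
        np.testing.assert_array_equal(predict_proba(ens, data),
                                      predict_proba(back, data))
        assert back.depths == ens.depths

    def test_version_mismatch_refused(self, tiny_ensemble, tmp_path):
        import joblib

        ens, _ = tiny_ensemble
        path = tmp_path / "model.joblib"
        save_model(ens, path)
        payload = joblib.load(path)
        payload["format_version"] = "0"
        joblib.dump(payload, path)
        with pytest.raises(ModelVersionError):
            load_model(path)
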