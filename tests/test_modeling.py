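"""Boosted ordinal scorers, gain ranking and LOOCV feature-count selection."""

import numpy as np
import pandas as pd
import pytest

from rigipose.errors import DegenerateTrainingError, LabelError, SchemaError
from rigipose.features import FeatureDescriptor, FeatureMatrix
from rigipose.modeling import (
    BoostedOrdinalScorer,
    GainSelectedScorer,
    ModelBundle,
    gain_contribution_matrix,
    rank_features_by_gain,
)


def _informative_matrix(n=60, n_noise=10, seed=0, names=None):
    """One feature exactly encodes the label; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, size=n)
    cols = {"signal": y + 0.01 * rng.normal(size=n)}
    for i in range(n_noise):
        name = names[i] if names else f"noise_{i:02d}"
        cols[name] = rng.normal(size=n)
    return pd.DataFrame(cols), y


class TestBoostedOrdinalScorer:
    def test_identical_fit_reproduces_gains_exactly(self):
        X, y = _informative_matrix(seed=5)
        g1 = BoostedOrdinalScorer(seed=3).fit(X, y).feature_gains_
        g2 = BoostedOrdinalScorer(seed=3).fit(X, y).feature_gains_
        assert (g1.to_numpy() == g2.to_numpy()).all()

    def test_separable_matrix_perfect_training_accuracy(self):
        X, y = _informative_matrix(seed=1)
        model = BoostedOrdinalScorer(seed=0).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_labels_error(self):
        X, _ = _informative_matrix(seed=2)
        with pytest.raises(DegenerateTrainingError):
            BoostedOrdinalScorer().fit(X, np.full(len(X), 2))

    def test_out_of_range_label_error(self):
        X, y = _informative_matrix(seed=2)
        y = y.copy()
        y[0] = 7
        with pytest.raises(LabelError):
            BoostedOrdinalScorer().fit(X, y)

    def test_score_four_merged_into_three(self):
        X, y = _informative_matrix(seed=2)
        y4 = np.where(y == 3, 4, y)
        model = BoostedOrdinalScorer(seed=0).fit(X, y4)
        assert set(model.classes_) <= {0, 1, 2, 3}

    def test_probabilities_sum_to_one(self):
        X, y = _informative_matrix(seed=4)
        model = BoostedOrdinalScorer(seed=0).fit(X, y)
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert proba.shape == (len(X), 4)

    def test_argmax_decision_with_low_tie_break(self):
        X, y = _informative_matrix(seed=4)
        model = BoostedOrdinalScorer(seed=0).fit(X, y)
        # decision rule itself, on hand-made probability rows
        rows = np.array([[0.1, 0.2, 0.6, 0.1], [0.4, 0.4, 0.1, 0.1]])
        assert int(np.argmax(rows[0])) == 2
        assert int(np.argmax(rows[1])) == 0  # lowest class wins the tie

    def test_missing_column_at_predict_errors(self):
        X, y = _informative_matrix(seed=4)
        model = BoostedOrdinalScorer(seed=0).fit(X, y)
        with pytest.raises(SchemaError, match="missing feature"):
            model.predict(X.drop(columns=["signal"]))

    def test_constant_column_does_not_change_predictions(self):
        X, y = _informative_matrix(seed=6)
        base = BoostedOrdinalScorer(seed=0).fit(X, y).predict(X)
        X2 = X.copy()
        X2["constant"] = 1.0
        aug = BoostedOrdinalScorer(seed=0).fit(X2, y).predict(X2)
        np.testing.assert_array_equal(base, aug)

    def test_row_permutation_invariance_without_bagging(self):
        X, y = _informative_matrix(seed=7)
        params = dict(bagging_fraction=1.0, feature_fraction=1.0, seed=0)
        base = BoostedOrdinalScorer(**params).fit(X, y)
        order = np.random.default_rng(0).permutation(len(X))
        perm = BoostedOrdinalScorer(**params).fit(X.iloc[order], y[order])
        np.testing.assert_allclose(
            base.predict_proba(X), perm.predict_proba(X), atol=1e-12
        )


class TestGainRanking:
    def test_informative_feature_ranks_first_across_seeds(self):
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            X, y = _informative_matrix(n=80, n_noise=50, seed=seed)
            model = BoostedOrdinalScorer(seed=seed).fit(X, y)
            if rank_features_by_gain(model.feature_gains_)[0] == "signal":
                wins += 1
        assert wins >= int(0.95 * n_seeds)

    def test_distinct_gains_strictly_descending(self):
        X, y = _informative_matrix(seed=3)
        model = BoostedOrdinalScorer(seed=0).fit(X, y)
        order = rank_features_by_gain(model.feature_gains_)
        gains = model.feature_gains_[order].to_numpy()
        assert (np.diff(gains) <= 0).all()

    def test_zero_gain_ties_lexicographic(self):
        gains = pd.Series({"b_feat": 0.0, "a_feat": 0.0, "top": 5.0})
        assert rank_features_by_gain(gains) == ["top", "a_feat", "b_feat"]


class TestGainSelectedScorer:
    def test_selection_recovers_small_feature_count(self):
        """With ~5 informative features the chosen k stays small and near-best."""
        rng = np.random.default_rng(21)
        n = 40
        y = rng.integers(0, 4, size=n)
        cols = {}
        for i in range(5):
            cols[f"inf_{i}"] = y * (1 + 0.2 * i) + 0.3 * rng.normal(size=n)
        for i in range(40):
            cols[f"noise_{i:02d}"] = rng.normal(size=n)
        X = pd.DataFrame(cols)
        scorer = GainSelectedScorer(
            grid=(5, 10, 15, 25), n_estimators=60, seed=0
        ).fit(X, y)
        assert scorer.selection_.chosen_k <= 15
        table = scorer.selection_.table.set_index("k")
        assert (
            table.loc[scorer.selection_.chosen_k, "acc0"]
            >= table["acc0"].max() - 0.05
        )

    def test_loocv_fold_count_equals_subjects(self):
        X, y = _informative_matrix(n=14, n_noise=4, seed=9)
        scorer = GainSelectedScorer(grid=(3,), n_estimators=30, seed=0).fit(X, y)
        assert scorer.loocv_predictions_.shape == (14,)

    def test_grid_clipped_with_warning(self):
        X, y = _informative_matrix(n=20, n_noise=3, seed=9)  # 4 columns
        with pytest.warns(UserWarning, match="clipped"):
            scorer = GainSelectedScorer(grid=(2, 50), n_estimators=30, seed=0).fit(
                X, y
            )
        assert max(scorer.selection_.table["k"]) <= 4

    def test_chosen_k_maximises_lexicographic_order(self):
        X, y = _informative_matrix(n=30, n_noise=10, seed=12)
        scorer = GainSelectedScorer(grid=(2, 5, 8), n_estimators=40, seed=0).fit(X, y)
        t = scorer.selection_.table
        chosen = t[t["k"] == scorer.selection_.chosen_k].iloc[0]
        best = t.sort_values(["acc0", "kappa", "k"],
                             ascending=[False, False, True]).iloc[0]
        assert (chosen["acc0"], chosen["kappa"]) == (best["acc0"], best["kappa"])


def _bundle_from(descs, n=40, seed=0, grid=(4,)):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, size=n)
    cols = {}
    for i, d in enumerate(descs):
        if i == 0:
            cols[d.full_name] = y + 0.05 * rng.normal(size=n)
        else:
            cols[d.full_name] = 0.5 * y + rng.normal(size=n)
    X = pd.DataFrame(cols)
    scorer = GainSelectedScorer(grid=grid, n_estimators=40, seed=seed).fit(X, y)
    return ModelBundle(target="PS", scorer=scorer, seed=seed)


class TestGainContributionMatrix:
    def _descs(self, motions_families):
        return [
            FeatureDescriptor(motion=m, channel="c", stat=s, family=f,
                              side_agg="unsided")
            for m, f, s in motions_families
        ]

    def test_single_motion_sums_to_100(self):
        descs = self._descs(
            [("GAIT", "position", "td_std"), ("GAIT", "angle", "td_q50"),
             ("GAIT", "kinematic", "kin_amp_mean"), ("GAIT", "position", "td_rms")]
        )
        matrix = gain_contribution_matrix(_bundle_from(descs))
        assert matrix.loc["GAIT"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_grand_total_is_100(self):
        descs = self._descs(
            [("GAIT", "position", "td_std"), ("LA", "angle", "td_q50"),
             ("TT", "kinematic", "kin_amp_mean"), ("POS", "position", "td_rms")]
        )
        matrix = gain_contribution_matrix(_bundle_from(descs))
        assert matrix.to_numpy().sum() == pytest.approx(100.0, abs=1e-6)


class TestModelBundle:
    def test_save_load_roundtrip_predictions(self, tmp_path):
        X, y = _informative_matrix(n=30, n_noise=6, seed=2)
        scorer = GainSelectedScorer(grid=(3, 5), n_estimators=40, seed=1).fit(X, y)
        bundle = ModelBundle(target="Rig-UE", scorer=scorer, seed=1)
        bundle.save(tmp_path / "m.json")
        back = ModelBundle.load(tmp_path / "m.json")
        np.testing.assert_array_equal(
            bundle.scorer.predict(X), back.scorer.predict(X)
        )
        assert back.target == "Rig-UE"
        assert back.scorer.selected_features_ == scorer.selected_features_
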