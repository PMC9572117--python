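import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_curve

from swaydetect import threshold as th
from swaydetect.threshold import BinaryVote, ThresholdModel


def _single_feature_model(thr=1.0, norm=2.0, direction=1, name="F"):
    return ThresholdModel(
        thresholds={name: thr},
        directions={name: direction},
        normalizers={name: norm},
        feature_order=(name,),
        or_groups=(),
    )


def _youden_oracle(values, labels):
    """Exhaustive Youden search over all cut-points and both orientations."""
    best = -np.inf
    uniq = np.unique(values)
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate([[uniq[0] - span], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + span]])
    pos = labels == 1
    for direction in (+1, -1):
        for t in candidates:
            votes = direction * (values - t) > 0
            j = votes[pos].mean() + (~votes[~pos]).mean() - 1.0
            best = max(best, j)
    return best


def _fitted_j(values, labels, model, name):
    d = model.directions[name]
    votes = d * (values - model.thresholds[name]) > 0
    pos = labels == 1
    return votes[pos].mean() + (~votes[~pos]).mean() - 1.0


class TestFitThresholds:
    def test_separable_feature_threshold_in_gap(self):
        df = pd.DataFrame({"F": [0.1, 0.2, 0.3, 2.1, 2.2]})
        labels = np.array([0, 0, 0, 1, 1])
        model = th.fit_thresholds(df, labels, feature_order=["F"], or_groups=[])
        assert 0.3 < model.thresholds["F"] < 2.1
        assert _fitted_j(df["F"].to_numpy(), labels, model, "F") == pytest.approx(1.0)

    def test_two_point_midpoint_rule(self):
        df = pd.DataFrame({"F": [0.0, 1.0]})
        model = th.fit_thresholds(df, np.array([0, 1]), feature_order=["F"], or_groups=[])
        assert model.thresholds["F"] == pytest.approx(0.5)

    def test_inverted_feature_gets_downward_direction(self):
        """Instability that drives a feature down (signed minima) is caught."""
        df = pd.DataFrame({"F": [-0.01, -0.02, -0.4, -0.5]})
        labels = np.array([0, 0, 1, 1])
        model = th.fit_thresholds(df, labels, feature_order=["F"], or_groups=[])
        assert model.directions["F"] == -1
        assert _fitted_j(df["F"].to_numpy(), labels, model, "F") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_youden_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        values = np.round(rng.normal(0, 1, n), 2)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        df = pd.DataFrame({"F": values})
        model = th.fit_thresholds(df, labels, feature_order=["F"], or_groups=[])
        assert _fitted_j(values, labels, model, "F") == pytest.approx(
            _youden_oracle(values, labels)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_upward_direction_matches_sklearn_roc(self, seed):
        """Independent cross-check against sklearn's ROC for separable data."""
        rng = np.random.default_rng(100 + seed)
        labels = np.repeat([0, 1], 25)
        values = np.concatenate([rng.normal(0, 1, 25), rng.normal(6, 1, 25)])
        fpr, tpr, thr = roc_curve(labels, values)
        sk_j = np.max(tpr - fpr)
        df = pd.DataFrame({"F": values})
        model = th.fit_thresholds(df, labels, feature_order=["F"], or_groups=[])
        assert _fitted_j(values, labels, model, "F") == pytest.approx(sk_j)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            th.fit_thresholds(pd.DataFrame({"F": [1.0, 2.0]}), [1, 1],
                              feature_order=["F"], or_groups=[])

    def test_constant_feature_warns(self):
        df = pd.DataFrame({"F": [1.0, 1.0, 1.0, 1.0]})
        with pytest.warns(RuntimeWarning, match="constant"):
            model = th.fit_thresholds(df, [0, 0, 1, 1], feature_order=["F"], or_groups=[])
        assert model.thresholds["F"] == 1.0


class TestBinarizeAndClassify:
    @pytest.fixture()
    def five_feature_model(self):
        names = ("A", "B", "C", "D", "E")
        return ThresholdModel(
            thresholds={n: 1.0 for n in names},
            directions={n: 1 for n in names},
            normalizers={n: 1.0 for n in names},
            feature_order=names,
            or_groups=(),
        )

    def test_all_below_gives_zero_votes(self, five_feature_model):
        vote = th.binarize({n: 0.0 for n in "ABCDE"}, five_feature_model)
        assert vote.fraction_over == 0.0
        assert th.classify(vote) == 0

    def test_majority_vote_classifies_unstable(self, five_feature_model):
        feats = {"A": 2.0, "B": 2.0, "C": 2.0, "D": 0.0, "E": 0.0}
        vote = th.binarize(feats, five_feature_model)
        assert th.classify(vote) == 1
        assert th.reliability_th(vote) == pytest.approx(20.0)

    def test_exact_half_counts_as_unstable(self):
        vote = BinaryVote(jfbin={"a": 1, "b": 1, "c": 0, "d": 0})
        assert th.classify(vote) == 1
        assert th.reliability_th(vote) == pytest.approx(0.0)

    def test_value_at_threshold_votes_stable(self, five_feature_model):
        vote = th.binarize({n: 1.0 for n in "ABCDE"}, five_feature_model)
        assert all(v == 0 for v in vote.jfbin.values())

    def test_or_group_fires_on_either_member(self):
        model = ThresholdModel(
            thresholds={"DAPmax": 1.0, "DMLmax": 1.0},
            directions={"DAPmax": 1, "DMLmax": 1},
            normalizers={"DAPmax": 1.0, "DMLmax": 1.0},
            feature_order=("DAPmax", "DMLmax"),
            or_groups=(("DAPmax", "DMLmax"),),
        )
        over_ap = th.binarize({"DAPmax": 2.0, "DMLmax": 0.0}, model)
        assert over_ap.jfbin == {"DAPmax|DMLmax": 1} and over_ap.n_effective == 1
        neither = th.binarize({"DAPmax": 0.5, "DMLmax": 0.5}, model)
        assert neither.jfbin == {"DAPmax|DMLmax": 0}

    def test_missing_feature_rejected(self, five_feature_model):
        with pytest.raises(ValueError, match="missing feature"):
            th.binarize({"A": 1.0}, five_feature_model)

    def test_unanimous_vote_reliability_is_100(self):
        assert th.reliability_th(BinaryVote(jfbin={"a": 1, "b": 1})) == 100.0
        assert th.reliability_th(BinaryVote(jfbin={"a": 0, "b": 0})) == 100.0


class TestReliabilityJf:
    def test_all_features_at_threshold_gives_zero(self):
        model = _single_feature_model()
        assert th.reliability_jf({"F": 1.0}, model, ps_pred=0) == 0.0

    def test_training_max_distance_gives_100(self):
        model = _single_feature_model(thr=1.0, norm=2.0)
        assert th.reliability_jf({"F": 3.0}, model, ps_pred=1) == pytest.approx(100.0)

    def test_half_distance_plus_disagreeing_feature(self):
        model = ThresholdModel(
            thresholds={"F": 0.0, "G": 0.0},
            directions={"F": 1, "G": 1},
            normalizers={"F": 1.0, "G": 1.0},
            feature_order=("F", "G"),
            or_groups=(),
        )
        # F aligned at half its training-max distance, G votes against
        ri = th.reliability_jf({"F": 0.5, "G": -0.8}, model, ps_pred=1)
        assert ri == pytest.approx(25.0)

    def test_jnd_clipped_beyond_training_range(self):
        model = _single_feature_model(thr=0.0, norm=1.0)
        assert th.reliability_jf({"F": 50.0}, model, ps_pred=1) == pytest.approx(100.0)

    def test_zero_normalizer_feature_skipped(self):
        model = ThresholdModel(
            thresholds={"F": 0.0, "G": 0.0},
            directions={"F": 1, "G": 1},
            normalizers={"F": 1.0, "G": 0.0},
            feature_order=("F", "G"),
            or_groups=(),
        )
        with pytest.warns(RuntimeWarning, match="zero normalizer"):
            ri = th.reliability_jf({"F": 1.0, "G": 5.0}, model, ps_pred=1)
        assert ri == pytest.approx(100.0)

    def test_monotone_in_aligned_feature(self):
        model = _single_feature_model(thr=0.0, norm=1.0)
        values = [th.reliability_jf({"F": v}, model, ps_pred=1) for v in (0.1, 0.4, 0.9, 2.0)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestEndToEnd:
    @pytest.fixture()
    def separable_table(self):
        rng = np.random.default_rng(0)
        n = 30
        stable = pd.DataFrame(
            {"A": rng.normal(0, 0.1, n), "B": rng.normal(0, 0.1, n), "C": rng.normal(0, 0.1, n)}
        )
        unstable = pd.DataFrame(
            {"A": rng.normal(5, 0.1, n), "B": rng.normal(5, 0.1, n), "C": rng.normal(5, 0.1, n)}
        )
        df = pd.concat([stable, unstable], ignore_index=True)
        labels = np.repeat([0, 1], n)
        return df, labels

    def test_separable_training_set_is_reproduced_unanimously(self, separable_table):
        df, labels = separable_table
        model = th.fit_thresholds(df, labels, feature_order=list(df.columns), or_groups=[])
        preds = th.predict_table(df, model)
        assert np.array_equal(preds["ps_pred"].to_numpy(), labels)
        assert np.all(preds["ri_th"].to_numpy() == 100.0)

    def test_ri_jf_invariant_under_feature_rescaling(self, separable_table):
        df, labels = separable_table
        m1 = th.fit_thresholds(df, labels, feature_order=list(df.columns), or_groups=[])
        df2 = df.copy()
        df2["A"] = df2["A"] * 1000.0
        m2 = th.fit_thresholds(df2, labels, feature_order=list(df.columns), or_groups=[])
        r1 = th.predict_table(df, m1)["ri_jf"].to_numpy()
        r2 = th.predict_table(df2, m2)["ri_jf"].to_numpy()
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_model_json_round_trip(self, tmp_path, separable_table):
        df, labels = separable_table
        model = th.fit_thresholds(df, labels, feature_order=list(df.columns), or_groups=[])
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ThresholdModel.from_json(path)
        assert loaded.thresholds == model.thresholds
        assert loaded.directions == model.directions
        assert loaded.or_groups == model.or_groups
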