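import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmfp.models import (
    NNModel,
    auc_by_kfsc,
    auc_vs_ptm_count_threshold,
    compare_auc,
    fit_single_feature_logistic,
    nn_forward,
    roc_auc,
    train_nn,
)
from ptmfp.simulate import simulate_feature_label_data


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        r = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties(self):
        r = roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 0])
        assert r.auc == 0.5

    def test_mixed_scores_equal_pairwise_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.6, 0.6, 0.05, 0.9]
        labels = [0, 1, 0, 1, 0, 0, 1, 0, 0, 1]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(0)
        r = roc_auc(rng.random(100), rng.integers(0, 2, 100))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        # stored AUC consistent with trapezoidal integral of the stored curve
        assert r.auc == pytest.approx(np.trapezoid(r.tpr, r.fpr), abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_rank_statistic_equals_brute_force(self, data):
        n = data.draw(st.integers(5, 200))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        scores = rng.choice(np.linspace(0, 1, 20), size=n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels)
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = np.r_[np.ones(20, int), np.zeros(40, int)]
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels).auc == pytest.approx(base)


class TestSingleFeatureLogistic:
    def test_constant_feature_gives_chance_auc(self):
        _, roc = fit_single_feature_logistic(np.ones(50), np.r_[np.ones(10), np.zeros(40)])
        assert roc.auc == 0.5

    def test_threshold_separable_gives_perfect_auc(self):
        x = np.r_[np.linspace(0, 1, 25), np.linspace(2, 3, 25)]
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        with pytest.warns(UserWarning, match="separation"):
            _, roc = fit_single_feature_logistic(x, y)
        assert roc.auc == 1.0

    def test_recovers_generative_slope(self):
        rng = np.random.default_rng(11)
        n = 20_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-2 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        model, _ = fit_single_feature_logistic(x, y)
        assert model.slope == pytest.approx(0.8, abs=0.1)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_single_feature_logistic(np.arange(5.0), np.ones(5, int))


class TestNNForward:
    def make_model(self, W1, b1, W2, b2, n_features):
        return NNModel(
            center=np.zeros(n_features), scale=np.ones(n_features),
            W1=np.asarray(W1, float), b1=np.asarray(b1, float),
            W2=np.asarray(W2, float), b2=float(b2),
        )

    def test_zero_weights_give_half(self):
        m = self.make_model(np.zeros((6, 3)), np.zeros(3), np.zeros(3), 0.0, 6)
        assert nn_forward(m, np.ones(6)) == 0.5

    def test_large_output_bias_saturates_toward_one(self):
        m = self.make_model(np.zeros((6, 3)), np.zeros(3), np.zeros(3), 30.0, 6)
        assert nn_forward(m, np.zeros(6)) > 0.999999

    def test_hand_computed_two_feature_network(self):
        W1 = [[0.5, -1.0], [0.25, 0.75]]
        b1 = [0.1, -0.2]
        W2 = [1.5, -0.5]
        b2 = 0.3
        m = self.make_model(W1, b1, W2, b2, 2)
        x = np.array([0.4, -1.2])
        h = np.tanh([0.5 * 0.4 + 0.25 * (-1.2) + 0.1, -1.0 * 0.4 + 0.75 * (-1.2) - 0.2])
        z = 1.5 * h[0] - 0.5 * h[1] + 0.3
        expected = 1 / (1 + np.exp(-z))
        assert nn_forward(m, x) == pytest.approx(expected, abs=1e-12)

    def test_output_strictly_inside_unit_interval(self):
        m = self.make_model(np.zeros((6, 3)), np.zeros(3), np.zeros(3), 1000.0, 6)
        p = nn_forward(m, np.zeros(6))
        assert 0.0 < p < 1.0

    def test_non_finite_input_errors(self):
        m = self.make_model(np.zeros((6, 3)), np.zeros(3), np.zeros(3), 0.0, 6)
        with pytest.raises(ValueError):
            nn_forward(m, np.array([np.nan, 0, 0, 0, 0, 0]))


class TestTraining:
    def test_null_labels_give_chance_validation_auc(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5000, 6))
        y = rng.integers(0, 2, 5000)
        _, _, roc_val = train_nn(X, y, seed=5)
        assert 0.45 <= roc_val.auc <= 0.55

    def test_identical_seed_identical_parameters(self):
        X, y, _ = simulate_feature_label_data(1500, seed=9)
        m1, _, _ = train_nn(X, y, seed=17)
        m2, _, _ = train_nn(X, y, seed=17)
        assert (m1.W1 == m2.W1).all() and (m1.W2 == m2.W2).all()
        assert (m1.b1 == m2.b1).all() and m1.b2 == m2.b2

    def test_too_few_samples_errors(self):
        X, y, _ = simulate_feature_label_data(100, seed=1)
        with pytest.raises(ValueError, match="samples"):
            train_nn(X, y, seed=0)

    def test_seed_stability_of_validation_auc(self):
        """Retraining with another seed moves validation AUC by < 0.02."""
        X, y, _ = simulate_feature_label_data(20_000, seed=21)
        _, _, rv_a = train_nn(X, y, seed=0)
        _, _, rv_b = train_nn(X, y, seed=1)
        assert abs(rv_a.auc - rv_b.auc) < 0.02

    def test_serialization_round_trip(self):
        X, y, _ = simulate_feature_label_data(1000, seed=2)
        model, _, _ = train_nn(X, y, seed=3)
        back = NNModel.from_json(model.to_json())
        x = X[:25]
        assert np.allclose(back.forward(x), model.forward(x))


class TestCompareAuc:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(1)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        stat, df, p = compare_auc(s, s, y)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_informative_vs_null_model_significant(self):
        X, y, p_true = simulate_feature_label_data(2000, seed=13)
        rng = np.random.default_rng(13)
        informative = p_true
        null = rng.random(2000)
        stat, _, p = compare_auc(informative, null, y)
        assert p < 0.01

    def test_invariant_to_monotone_transform(self):
        X, y, p_true = simulate_feature_label_data(500, seed=8)
        rng = np.random.default_rng(8)
        other = rng.random(500)
        stat1, _, p1 = compare_auc(p_true, other, y)
        stat2, _, p2 = compare_auc(np.log(p_true), 5 * other - 2, y)
        assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)

    def test_unpaired_inputs_error(self):
        with pytest.raises(ValueError):
            compare_auc([0.1, 0.2], [0.3], [1, 0])


class TestThresholdSweep:
    def test_restriction_keeps_pc_up_to_threshold(self):
        X, y, _ = simulate_feature_label_data(3000, seed=4)
        table = auc_vs_ptm_count_threshold(X, y, thresholds=[3], seed=0)
        assert table.loc[0, "n"] == int(((X[:, 0] >= 1) & (X[:, 0] <= 3)).sum())

    def test_pc_only_auc_is_half_at_threshold_one(self):
        X, y, _ = simulate_feature_label_data(3000, seed=4)
        table = auc_vs_ptm_count_threshold(X, y, thresholds=[1], seed=0)
        assert table.loc[0, "auc_pc"] == 0.5

    def test_vacuous_restriction_equals_full_set(self):
        X, y, _ = simulate_feature_label_data(2000, seed=6)
        t_max = int(X[:, 0].max())
        table = auc_vs_ptm_count_threshold(X, y, thresholds=[t_max], seed=0)
        from ptmfp.models import fit_single_feature_logistic as fsl

        _, roc_full = fsl(X[:, 1], y)
        assert table.loc[0, "auc_sasa"] == pytest.approx(roc_full.auc)


class TestAucByKfsc:
    def test_monotone_fixture_gives_increasing_auc(self):
        """Positives given systematically higher scores at higher KFSC."""
        rng = np.random.default_rng(3)
        bins = ["1", "2", "3", "4", "5-10", "11+"]
        scores, labels, kfsc = [], [], []
        for i, b in enumerate(bins):
            scores += list(0.3 + 0.1 * i + 0.02 * rng.random(30))
            labels += [1] * 30
            kfsc += [b] * 30
        scores += list(rng.random(600))
        labels += [0] * 600
        kfsc += [None] * 600
        table = auc_by_kfsc(np.array(scores), np.array(labels), kfsc)
        aucs = table["auc"].to_numpy()
        assert (np.diff(aucs) > 0).all()

    def test_single_positive_closed_form(self):
        scores = np.array([0.9, 0.1, 0.5, 0.9, 0.95])
        labels = np.array([1, 0, 0, 0, 0])
        kfsc = ["2", None, None, None, None]
        table = auc_by_kfsc(scores, labels, kfsc)
        row = table[table.kfsc_bin == "2"].iloc[0]
        # outscores 0.1 and 0.5, ties 0.9, loses to 0.95 -> (2 + 0.5) / 4
        assert row.auc == pytest.approx(2.5 / 4)
        assert np.isnan(table[table.kfsc_bin == "1"].iloc[0].auc)

    def test_uninformative_scores_near_half_everywhere(self):
        rng = np.random.default_rng(12)
        n = 4000
        labels = (rng.random(n) < 0.2).astype(int)
        kfsc = [rng.choice(["1", "2", "3", "4", "5-10", "11+"]) if l else None
                for l in labels]
        table = auc_by_kfsc(rng.random(n), labels, kfsc)
        assert np.nanmax(np.abs(table["auc"].to_numpy() - 0.5)) < 0.08
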