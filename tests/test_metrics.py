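import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsesite import (
    ConfusionCounts,
    CvConfig,
    PlantedSignalParams,
    TreeParams,
    accuracy,
    auc,
    confusion,
    fpr,
    implied_confusion,
    kfold_cv,
    make_labeled_dataset,
    mcc,
    roc_curve,
    round_metric,
    sensitivity,
    specificity,
)
from oracles import pair_count_auc

counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
)


class TestConfusion:
    def test_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_all_positive_prediction(self):
        c = confusion([1, 0, 0], [1, 1, 1])
        assert c.tn == 0 and c.fn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestRatioMetrics:
    def test_sensitivity_of_published_style_counts(self):
        # 698 of 780 positives recovered
        assert round_metric(sensitivity(ConfusionCounts(698, 0, 0, 82))) == 0.895
        # 418 of 780
        assert round_metric(sensitivity(ConfusionCounts(418, 0, 0, 362))) == 0.536

    def test_specificity_symmetry(self):
        assert specificity(ConfusionCounts(0, 30, 30, 0)) == 0.5

    def test_spec_plus_fpr_is_one(self):
        c = ConfusionCounts(10, 7, 33, 2)
        assert specificity(c) + fpr(c) == pytest.approx(1.0)

    def test_zero_denominators_reported_as_none(self):
        no_pos = ConfusionCounts(0, 5, 5, 0)
        assert sensitivity(no_pos) is None
        no_neg = ConfusionCounts(5, 0, 0, 5)
        assert specificity(no_neg) is None and fpr(no_neg) is None
        assert mcc(ConfusionCounts(5, 0, 0, 0)) is None

    @settings(max_examples=200, deadline=None)
    @given(counts=counts_strategy)
    def test_accuracy_identity(self, counts):
        tp, fp, tn, fn = counts
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.n_pos == 0 or c.n_neg == 0:
            return
        expected = (sensitivity(c) * c.n_pos + specificity(c) * c.n_neg) / (
            c.n_pos + c.n_neg
        )
        assert accuracy(c) == pytest.approx(expected)


class TestMcc:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(tp=418, fp=62, tn=718, fn=362), 0.494),
            (ConfusionCounts(tp=698, fp=82, tn=698, fn=82), 0.790),
        ],
    )
    def test_three_decimal_values(self, c, expected):
        assert round_metric(mcc(c)) == pytest.approx(expected)

    def test_perfect_confusion_is_one(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=10, fn=0)) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None)
    @given(counts=counts_strategy)
    def test_bounds_and_swap_invariance(self, counts):
        tp, fp, tn, fn = counts
        c = ConfusionCounts(tp, fp, tn, fn)
        value = mcc(c)
        if value is None:
            return
        assert -1.0 <= value <= 1.0
        # simultaneous TP<->TN, FP<->FN swap leaves MCC unchanged
        swapped = ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)
        assert mcc(swapped) == pytest.approx(value)
        if value == 1.0:
            assert fp == 0 and fn == 0

    def test_label_swap_exchanges_sens_and_spec(self):
        c = ConfusionCounts(tp=40, fp=10, tn=35, fn=15)
        flipped = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
        assert sensitivity(flipped) == specificity(c)
        assert specificity(flipped) == sensitivity(c)
        assert mcc(flipped) == pytest.approx(mcc(c))


class TestImpliedConfusion:
    def test_published_style_rows(self):
        c = implied_confusion(0.536, 0.921, 780, 780)
        assert (c.tp, c.tn) == (418, 718)
        c = implied_confusion(0.895, 0.895, 780, 780)
        assert c.tp == c.tn == 698
        c = implied_confusion(1.0, 1.0, 10, 10)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_half_rounds_away_from_zero(self):
        assert implied_confusion(0.5, 0.0, 1, 1).tp == 1  # 0.5 -> 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            implied_confusion(1.2, 0.5, 10, 10)


class TestRoundMetric:
    @pytest.mark.parametrize(
        "x,expected", [(0.0005, 0.001), (-0.0005, -0.001), (0.8945, 0.895), (None, None)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_metric(x) == expected


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_curve([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert auc(curve) == pytest.approx(1.0)

    def test_all_tied_scores(self):
        curve = roc_curve([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc(curve) == pytest.approx(0.5)

    def test_endpoints(self):
        rng = np.random.default_rng(0)
        curve = roc_curve(rng.integers(0, 2, 30), rng.uniform(size=30))
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(curve.fpr) >= 0).all()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 1], [0.2, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        # coarse scores force ties, exercising the half-credit correction
        scores = rng.uniform(size=50).round(1)
        assert auc(roc_curve(y, scores)) == pytest.approx(
            pair_count_auc(y, scores), abs=1e-12
        )


@pytest.fixture(scope="module")
def balanced_dataset():
    return make_labeled_dataset(
        PlantedSignalParams(n_pos=780, n_neg=780, effect_size=3.0, seed=11)
    )


class TestKfoldCv:
    def test_fold_sizes_six(self, balanced_dataset):
        result = kfold_cv(balanced_dataset, cv=CvConfig(k=6, seed=1))
        assert [f.n_test for f in result.folds] == [260] * 6

    def test_fold_sizes_eight(self, balanced_dataset):
        result = kfold_cv(balanced_dataset, cv=CvConfig(k=8, seed=1))
        assert [f.n_test for f in result.folds] == [195] * 8

    def test_same_seed_same_reports(self, balanced_dataset):
        a = kfold_cv(balanced_dataset, cv=CvConfig(k=6, seed=7))
        b = kfold_cv(balanced_dataset, cv=CvConfig(k=6, seed=7))
        assert a.mean == b.mean
        assert [f.report for f in a.folds] == [f.report for f in b.folds]
        np.testing.assert_array_equal(a.mean_tpr, b.mean_tpr)

    def test_roc_grid_shape_and_range(self, balanced_dataset):
        result = kfold_cv(balanced_dataset, cv=CvConfig(k=6, seed=1))
        assert result.fpr_grid.shape == result.mean_tpr.shape == (101,)
        assert (result.std_tpr >= 0).all()
        assert 0.0 <= result.mean_tpr.min() and result.mean_tpr.max() <= 1.0

    def test_pooled_counts_cover_every_sample(self, balanced_dataset):
        result = kfold_cv(balanced_dataset, cv=CvConfig(k=6, seed=1))
        c = result.pooled_counts
        assert c.n_pos == 780 and c.n_neg == 780

    def test_k_exceeding_class_count_rejected(self):
        small = make_labeled_dataset(PlantedSignalParams(n_pos=3, n_neg=30, seed=0))
        with pytest.raises(ValueError):
            kfold_cv(small, cv=CvConfig(k=5))

    def test_strong_signal_gives_high_auc(self, balanced_dataset):
        result = kfold_cv(
            balanced_dataset, TreeParams(), CvConfig(k=6, seed=1)
        )
        assert result.mean["auc"] > 0.9
        assert result.mean["accuracy"] > 0.85


def test_cv_config_validation():
    with pytest.raises(ValueError):
        CvConfig(k=1)
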