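import numpy as np
import pandas as pd
import pytest

from wbdecon import (
    DiseaseSpec,
    ValidationError,
    auc,
    audit_leakage,
    combine_posteriors,
    default_benchmark,
    evaluate_disease_specific,
    make_basis,
    predict_posterior,
    robust_gene_list,
    select_top_features,
    simulate_collection,
    train_branch,
)
from wbdecon.classify import TrainedBranch


def _labels(frame, positives):
    return pd.Series(
        [c in positives for c in frame.columns], index=frame.columns
    )


class TestSelectTopFeatures:
    def _toy(self):
        # f_strong separates the groups widely, f_mid moderately,
        # f_null not at all
        cols = [f"s{i}" for i in range(8)]
        frame = pd.DataFrame(
            {
                "f_mid": [1, 2, 1.5, 1.8, 2.5, 3.1, 2.8, 3.0],
                "f_null": [1, 1.1, 0.9, 1.0, 1.02, 0.95, 1.05, 1.0],
                "f_strong": [0, 0.1, 0.05, 0.02, 5, 5.1, 4.9, 5.2],
            },
            index=cols,
        ).T
        labels = _labels(frame, cols[4:])
        return frame, labels

    def test_ranking_by_absolute_welch_t(self):
        frame, labels = self._toy()
        assert select_top_features(frame, labels, 2) == ["f_strong", "f_mid"]

    def test_n_top_beyond_available_returns_all_ranked(self):
        frame, labels = self._toy()
        assert select_top_features(frame, labels, 10) == [
            "f_strong", "f_mid", "f_null"
        ]

    def test_tied_features_break_by_id(self):
        frame, labels = self._toy()
        dup = frame.loc[["f_mid", "f_mid"]]
        dup.index = ["x2", "x1"]
        assert select_top_features(dup, labels, 2) == ["x1", "x2"]

    def test_single_class_rejected(self):
        frame, labels = self._toy()
        with pytest.raises(ValidationError):
            select_top_features(frame, labels & False, 2)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_all_tied_scores_give_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([1, 2], [1, 1])


class TestCombinePosteriors:
    def test_elementwise_product(self):
        assert combine_posteriors([0.8], [0.5])[0] == pytest.approx(0.4)

    def test_ones_are_identity(self):
        p = np.array([0.2, 0.7])
        assert np.allclose(combine_posteriors(p, np.ones(2)), p)

    def test_zero_absorbs(self):
        assert combine_posteriors([0.0], [0.9])[0] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            combine_posteriors([0.1], [0.1, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            combine_posteriors([1.5], [0.5])


class TestTrainBranch:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(40)]
        informative = np.r_[rng.normal(-2, 0.5, 20), rng.normal(2, 0.5, 20)]
        noise = rng.normal(0, 1, size=(4, 40))
        frame = pd.DataFrame(
            np.vstack([informative, noise]),
            index=["inf", "n1", "n2", "n3", "n4"],
            columns=cols,
        )
        return frame, _labels(frame, cols[20:])

    def test_separable_toy_scores_positives_high(self):
        frame, labels = self._separable()
        branch = train_branch(frame, labels, inner_folds=3, seed=1,
                              l1_ratios=(0.0, 1.0), Cs=(0.1, 1.0))
        post = predict_posterior(branch, frame)
        assert (post[labels] > 0.5).all()
        assert (post[~labels] < 0.5).all()

    def test_same_seed_selects_same_hyperparameters(self):
        frame, labels = self._separable()
        kw = dict(inner_folds=3, seed=7, l1_ratios=(0.0, 0.5, 1.0),
                  Cs=(0.1, 1.0))
        a = train_branch(frame, labels, **kw)
        b = train_branch(frame, labels, **kw)
        assert (a.l1_ratio, a.C) == (b.l1_ratio, b.C)
        assert np.allclose(a.model.coef_, b.model.coef_)

    def test_uninformative_rows_give_near_prior_posterior(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(30)]
        frame = pd.DataFrame(
            np.tile(rng.normal(size=(3, 1)), (1, 30)), columns=cols,
            index=["a", "b", "c"],
        )
        labels = _labels(frame, cols[:15])  # balanced -> prior 0.5
        branch = train_branch(frame, labels, inner_folds=3, seed=3,
                              l1_ratios=(0.0,), Cs=(1.0,))
        post = predict_posterior(branch, frame)
        assert np.allclose(post, 0.5, atol=0.05)
        assert post.nunique() == 1  # identical samples, identical posterior

    def test_missing_feature_at_prediction_is_error(self):
        frame, labels = self._separable()
        branch = train_branch(frame, labels, inner_folds=3, seed=1,
                              l1_ratios=(0.0,), Cs=(1.0,))
        with pytest.raises(ValidationError, match="inf"):
            predict_posterior(branch, frame.drop(index="inf"))

    def test_posterior_monotone_in_positive_weight(self):
        frame, labels = self._separable()
        branch = train_branch(frame, labels, inner_folds=3, seed=1,
                              l1_ratios=(0.0,), Cs=(1.0,))
        w = branch.coefficients["inf"]
        assert w > 0
        bumped = frame.copy()
        bumped.loc["inf"] += 1.0
        p0 = predict_posterior(branch, frame)
        p1 = predict_posterior(branch, bumped)
        assert (p1 >= p0 - 1e-12).all()


class TestRobustGeneList:
    def _branch(self, coefs):
        class _Stub:
            def __init__(self, c):
                self.coef_ = np.array([c])
        return TrainedBranch(
            feature_ids=list(coefs),
            model=_Stub(list(coefs.values())),
            l1_ratio=0.5, C=1.0, inner_auc=0.9,
        )

    def test_strict_majority_rule(self):
        runs = (
            [self._branch({"g1": 1.0, "g2": 0.5})] * 6
            + [self._branch({"g1": 0.0, "g2": 0.3})] * 4
        )
        out = robust_gene_list(runs)
        assert "g2" in out  # 10/10
        assert "g1" in out  # 6/10
        runs5 = (
            [self._branch({"g1": 1.0})] * 5
            + [self._branch({"g1": 0.0})] * 5
        )
        assert robust_gene_list(runs5) == []  # exactly half is excluded

    def test_sorted_by_frequency_then_id(self):
        runs = (
            [self._branch({"b": 1.0, "a": 1.0, "c": 1.0})] * 6
            + [self._branch({"b": 1.0, "a": 0.0, "c": 1.0})] * 4
        )
        assert robust_gene_list(runs) == ["b", "c", "a"]

    def test_requires_at_least_two_runs(self):
        with pytest.raises(ValidationError):
            robust_gene_list([self._branch({"g": 1.0})])


@pytest.fixture(scope="module")
def tiny_collection():
    """Two diseases x two datasets, small enough for fast evaluation."""
    basis, markers = make_basis(80, ["A", "B"], 4, 30.0, seed=31)
    specs = [
        (DiseaseSpec("flu", {"A": 0.6},
                     [("A", g, 2.5) for g in basis.gene_ids[40:46]]),
         2, (10, 10)),
        (DiseaseSpec("tb", {"B": 0.6},
                     [("B", g, 2.5) for g in basis.gene_ids[50:56]]),
         2, (10, 10)),
    ]
    coll = simulate_collection(specs, basis, [2.0, 2.0], noise_cv=0.1,
                               batch_scale_sd=0.2, seed=32)
    return [ds for ds, _ in coll], markers


class TestEvaluationSchema:
    def test_oracle_scores_give_perfect_auc(self, tiny_collection):
        datasets, markers = tiny_collection
        truth = pd.concat([ds.annotations for ds in datasets])

        def oracle(ids):
            return np.array(
                [float(truth.loc[s, "disease"] == "flu"
                       and truth.loc[s, "group"] == "case") for s in ids]
            )

        res = evaluate_disease_specific(
            datasets, "flu", features=("original",), n_top=5,
            outer_repeats=1, n_subfolds=5, seed=1, oracle=oracle,
        )
        assert res.rounds["auc"].min() == 1.0

    def test_no_positive_dataset_overlap_between_train_and_test(
        self, tiny_collection
    ):
        datasets, markers = tiny_collection
        res = evaluate_disease_specific(
            datasets, "flu", features=("cell_component",), markers=markers,
            n_top=5, outer_repeats=1, n_subfolds=5, seed=2,
        )
        assert audit_leakage(res) == []
        for a in res.audits:
            assert not (a.param_fit & a.test)
            assert not (a.train_pos_datasets & a.test_pos_datasets)

    def test_single_dataset_disease_rejected(self, tiny_collection):
        datasets, markers = tiny_collection
        with pytest.raises(ValidationError, match="independent datasets"):
            evaluate_disease_specific(datasets[:3], "tb", markers=markers)

    def test_rounds_cover_every_heldout_dataset_and_fold(
        self, tiny_collection
    ):
        datasets, markers = tiny_collection
        res = evaluate_disease_specific(
            datasets, "flu", features=("cell_component",), markers=markers,
            n_top=5, outer_repeats=1, n_subfolds=5, seed=2,
        )
        seen = set(
            zip(res.rounds["held_out_dataset"], res.rounds["fold"])
        )
        assert seen == {
            (d, f) for d in ["flu.d1", "flu.d2"] for f in range(5)
        }
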