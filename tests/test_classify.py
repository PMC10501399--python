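"""Classifier configs, fold planning, scoring, and issue assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdad.classify import (
    CLASSIFIER_KINDS,
    ClassifierConfig,
    FoldSkip,
    default_configs,
    fit_predict,
)
from emdad.evaluate import (
    ConfusionCounts,
    PlanningError,
    best_combinations,
    evaluate_matrix,
    make_issue_dataset,
    plan_cv,
    report,
    run_issue,
    score,
)
from emdad.features import FeatureMatrix, feature_columns


def _fm(values, labels, subjects, feature_name="lbp"):
    n_ch = values.shape[1] // 8
    return FeatureMatrix(
        values=values,
        feature_name=feature_name,
        column_labels=feature_columns(tuple(f"ch{i}" for i in range(n_ch))),
        labels=tuple(labels),
        subject_ids=tuple(subjects),
    )


def _blobs(rng, n_per=30, dim=16, sep=6.0):
    """Two well-separated Gaussian classes (Bayes-separable by construction)."""
    a = rng.standard_normal((n_per, dim))
    b = rng.standard_normal((n_per, dim))
    b[:, 0] += sep
    X = np.vstack([a, b])
    y = np.array(["neurotypical"] * n_per + ["mild_ad"] * n_per)
    return X, y


class TestConfigs:
    def test_every_kind_has_complete_defaults(self):
        for cfg in default_configs(seed=1):
            assert cfg.hyperparameters  # merged defaults always present
        ann = ClassifierConfig("ann")
        for key in ("hidden_layers", "nodes", "hidden_activation",
                    "output_activation", "loss", "trainer", "epochs",
                    "learning_rate"):
            assert key in ann.hyperparameters

    def test_overrides_merge_without_losing_defaults(self):
        cfg = ClassifierConfig("cnn", {"epochs": 3})
        assert cfg.hyperparameters["epochs"] == 3
        assert cfg.hyperparameters["n_filters"] == 96

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig("random_forest")


FAST_NET = {
    "ann": {"epochs": 200},
    "rnn": {"epochs": 100},
    "cnn": {"epochs": 8, "n_filters": 4, "batch_size": 16},
}


class TestFitPredict:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_blobs_classified_correctly(self, rng, kind):
        X, y = _blobs(rng)
        cfg = ClassifierConfig(kind, FAST_NET.get(kind, {}), seed=0)
        pred = fit_predict(cfg, X, y, X)
        if kind in ("lda", "svm", "adaboost_tree"):
            # closed-form / margin learners separate the blobs exactly
            assert np.mean(pred == y) == 1.0
        else:
            # gradient-trained nets at reduced epochs: near-perfect
            assert np.mean(pred == y) >= 0.95

    def test_single_class_fold_skipped(self, rng):
        X = rng.standard_normal((10, 16))
        y = np.array(["mild_ad"] * 10)
        with pytest.raises(FoldSkip):
            fit_predict(ClassifierConfig("lda"), X, y, X)

    @pytest.mark.parametrize("kind", ["lda", "svm"])
    def test_training_order_invariance(self, rng, kind):
        X, y = _blobs(rng, n_per=20)
        perm = rng.permutation(len(y))
        Xt = rng.standard_normal((8, 16))
        cfg = ClassifierConfig(kind, seed=0)
        assert np.array_equal(
            fit_predict(cfg, X, y, Xt), fit_predict(cfg, X[perm], y[perm], Xt)
        )

    @pytest.mark.parametrize("kind", ["ann", "rnn", "cnn"])
    def test_net_determinism_given_seed(self, rng, kind):
        X, y = _blobs(rng, n_per=15)
        Xt = rng.standard_normal((6, 16))
        cfg = ClassifierConfig(kind, FAST_NET[kind], seed=3)
        assert np.array_equal(
            fit_predict(cfg, X, y, Xt), fit_predict(cfg, X, y, Xt)
        )

    def test_three_class_nets(self, rng):
        # the nets must handle the 3-class issue, not just binary
        X = np.vstack([rng.standard_normal((15, 16)) + off
                       for off in (0.0, 6.0, 12.0)])
        y = np.repeat(["neurotypical", "mild_ad", "moderate_ad"], 15)
        cfg = ClassifierConfig("ann", FAST_NET["ann"], seed=0)
        pred = fit_predict(cfg, X, y, X)
        assert np.mean(pred == y) > 0.95


class TestScore:
    def test_enumerated_confusion_arithmetic(self):
        # worked example: TP=9 FP=1 TN=8 FN=2
        y_true = ["p"] * 11 + ["n"] * 9
        y_pred = ["p"] * 9 + ["n"] * 2 + ["p"] * 1 + ["n"] * 8
        counts, m = score(y_true, y_pred, positive_class="p")
        assert counts.binary_counts() == (9, 1, 8, 2)
        assert m["precision"] == pytest.approx(90.0)
        assert m["recall"] == pytest.approx(9 / 11 * 100)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_perfect_prediction(self):
        y = ["a", "b", "a", "b"]
        _, m = score(y, y, positive_class="b")
        assert m["precision"] == m["recall"] == m["accuracy"] == 100.0

    def test_all_one_class_on_balanced_binary(self):
        y_true = ["p"] * 5 + ["n"] * 5
        y_pred = ["n"] * 10
        _, m = score(y_true, y_pred, positive_class="p")
        assert m["accuracy"] == 50.0
        assert m["recall"] == 0.0
        assert m["precision"] == 0.0
        assert "undefined_precision" in m["flags"]

    def test_exhaustive_small_tables_match_direct_arithmetic(self):
        for tp in range(0, 11, 2):
            for fp in range(0, 11, 2):
                for tn in range(0, 11, 2):
                    for fn in range(0, 11, 2):
                        if tp + fp + tn + fn == 0:
                            continue
                        y_true = ["p"] * (tp + fn) + ["n"] * (fp + tn)
                        y_pred = (["p"] * tp + ["n"] * fn
                                  + ["p"] * fp + ["n"] * tn)
                        _, m = score(y_true, y_pred, positive_class="p",
                                     classes=("n", "p"))
                        exp_prec = tp / (tp + fp) * 100 if tp + fp else 0.0
                        exp_rec = tp / (tp + fn) * 100 if tp + fn else 0.0
                        exp_acc = (tp + tn) / (tp + fp + tn + fn) * 100
                        assert m["precision"] == pytest.approx(exp_prec)
                        assert m["recall"] == pytest.approx(exp_rec)
                        assert m["accuracy"] == pytest.approx(exp_acc)

    def test_macro_metrics_three_class(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "c", "a"]
        counts, m = score(y_true, y_pred)
        assert counts.matrix.sum() == 6
        assert m["accuracy"] == pytest.approx(4 / 6 * 100)
        # per-class precision: a: 1/2, b: 2/3, c: 1/1
        assert m["precision"] == pytest.approx((1 / 2 + 2 / 3 + 1) / 3 * 100)
        # per-class recall: a: 1/2, b: 2/2, c: 1/2
        assert m["recall"] == pytest.approx((1 / 2 + 1 + 1 / 2) / 3 * 100)


class TestIssues:
    def _cohort_fm(self, rng, per_class=(10, 8, 6)):
        labels, subjects = [], []
        for lbl, n in zip(("neurotypical", "mild_ad", "moderate_ad"), per_class):
            for i in range(n):
                labels.append(lbl)
                subjects.append(f"{lbl}-s{i % 3}")
        values = rng.standard_normal((len(labels), 16))
        return _fm(values, labels, subjects)

    def test_issue_iv_merges_ad_classes(self, rng):
        fm = self._cohort_fm(rng)
        sub, positive = make_issue_dataset(fm, "IV")
        assert positive == "ad"
        assert sub.labels.count("neurotypical") == 10
        assert sub.labels.count("ad") == 14

    def test_issue_i_excludes_moderate(self, rng):
        sub, _ = make_issue_dataset(self._cohort_fm(rng), "I")
        assert set(sub.labels) == {"neurotypical", "mild_ad"}
        assert sub.n_trials == 18

    def test_issue_v_preserves_everything(self, rng):
        fm = self._cohort_fm(rng)
        sub, positive = make_issue_dataset(fm, "V")
        assert positive is None
        assert sub.n_trials == fm.n_trials

    def test_missing_class_rejected(self, rng):
        fm = self._cohort_fm(rng, per_class=(10, 8, 0))
        with pytest.raises(ValueError, match="missing class"):
            make_issue_dataset(fm, "II")


class TestCVPlans:
    def _fm_subjects(self, rng, subjects_per_class=5, trials=4):
        labels, subjects = [], []
        for lbl in ("neurotypical", "mild_ad", "moderate_ad"):
            for s in range(subjects_per_class):
                for _ in range(trials):
                    labels.append(lbl)
                    subjects.append(f"{lbl}-s{s}")
        return _fm(rng.standard_normal((len(labels), 16)), labels, subjects)

    def test_kfold_partition_sizes(self, rng):
        fm = self._fm_subjects(rng)
        plan = plan_cv(fm, "kfold", k=10, seed=0)
        sizes = [len(te) for _, te in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        all_test = np.concatenate([te for _, te in plan.folds])
        assert sorted(all_test) == list(range(fm.n_trials))

    def test_loso_no_subject_crossing(self, rng):
        fm = self._fm_subjects(rng)
        plan = plan_cv(fm, "loso", seed=0)
        subj = np.asarray(fm.subject_ids)
        assert len(plan.folds) == 5
        for train, test in plan.folds:
            assert not set(subj[train]) & set(subj[test])
        all_test = np.concatenate([te for _, te in plan.folds])
        assert sorted(all_test) == list(range(fm.n_trials))

    def test_loso_holds_out_one_subject_per_class_at_five(self, rng):
        fm = self._fm_subjects(rng, subjects_per_class=5)
        plan = plan_cv(fm, "loso", seed=2)
        subj = np.asarray(fm.subject_ids)
        labels = np.asarray(fm.labels)
        for _, test in plan.folds:
            for lbl in set(labels):
                held = {s for s in subj[test] if s.startswith(lbl)}
                assert len(held) == 1

    def test_loso_infeasible_names_limiting_class(self, rng):
        fm = self._fm_subjects(rng, subjects_per_class=3)
        with pytest.raises(PlanningError, match="mild_ad|neurotypical|moderate_ad"):
            plan_cv(fm, "loso", seed=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_invariants_for_any_seed(self, seed):
        rng = np.random.default_rng(99)
        fm = self._fm_subjects(rng, subjects_per_class=5, trials=3)
        kf = plan_cv(fm, "kfold", k=10, seed=seed)
        sizes = [len(te) for _, te in kf.folds]
        assert max(sizes) - min(sizes) <= 1
        lo = plan_cv(fm, "loso", seed=seed)
        subj = np.asarray(fm.subject_ids)
        for train, test in lo.folds:
            assert not set(subj[train]) & set(subj[test])


class TestRunAndReport:
    def _matrices(self, rng):
        labels, subjects = [], []
        values = []
        for ci, lbl in enumerate(("neurotypical", "mild_ad", "moderate_ad")):
            for s in range(5):
                for _ in range(4):
                    labels.append(lbl)
                    subjects.append(f"{lbl}-s{s}")
                    values.append(rng.standard_normal(16) + 4.0 * ci)
        fm = _fm(np.array(values), labels, subjects)
        return {"lbp": fm}

    def test_record_count_and_determinism(self, rng):
        mats = self._matrices(rng)
        cfgs = default_configs(("lda", "svm"), seed=0)
        recs = run_issue(mats, "I", cfgs, schemes=("kfold", "loso"), k=5, seed=1)
        assert len(recs) == 1 * 2 * 2  # features x classifiers x schemes
        recs2 = run_issue(mats, "I", cfgs, schemes=("kfold", "loso"), k=5, seed=1)
        for a, b in zip(recs, recs2):
            assert a.accuracy == b.accuracy

    def test_separated_classes_score_highly(self, rng):
        mats = self._matrices(rng)
        recs = run_issue(mats, "V", default_configs(("lda",), seed=0),
                         schemes=("kfold",), k=5, seed=0)
        assert recs[0].accuracy >= 90.0

    def test_averages_equal_fold_means(self, rng):
        mats = self._matrices(rng)
        recs = run_issue(mats, "II", default_configs(("lda",), seed=0),
                         schemes=("kfold",), k=5, seed=0)
        r = recs[0]
        assert r.accuracy == pytest.approx(
            np.mean([f["accuracy"] for f in r.per_fold]), abs=1e-9
        )
        assert 0 <= r.precision <= 100 and 0 <= r.recall <= 100

    def test_report_layout_and_roundtrip(self, rng, tmp_path):
        from emdad.evaluate import write_report
        import pandas as pd

        mats = self._matrices(rng)
        recs = run_issue(mats, "I", default_configs(("lda",), seed=0),
                         schemes=("kfold",), k=5, seed=0)
        tables = report(recs)
        df = tables[("I", "kfold")]
        assert ("lda", "Acc.") in df.columns
        assert list(df.index) == ["lbp"]
        paths = write_report(recs, tmp_path)
        back = pd.read_csv(paths[0], header=[0, 1], index_col=0)
        assert back.loc["lbp", ("lda", "Acc.")] == pytest.approx(
            recs[0].accuracy
        )
        best = best_combinations(recs)
        assert best.loc[0, "issue"] == "I"

    def test_empty_records_give_header_only(self):
        tables = report([])
        assert list(tables.values())[0].empty
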