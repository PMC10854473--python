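import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from cdtl import (ConfusionMatrix, FeatureMatrix, SliceRecord, SliceSet,
                  ValidationError, auc_mann_whitney, auc_with_ci, confusion,
                  evaluate_predictions, metrics, oversample,
                  stratified_summary)


class TestConfusion:
    def test_perfect_predictions_on_diagonal(self):
        y = ["p"] * 6 + ["n"] * 4
        conf = confusion(y, y, positive="p")
        assert (conf.tp, conf.fn, conf.fp, conf.tn) == (6, 0, 0, 4)

    def test_flipped_predictions_on_antidiagonal(self):
        y = ["p"] * 6 + ["n"] * 4
        flipped = ["n"] * 6 + ["p"] * 4
        conf = confusion(y, flipped, positive="p")
        assert (conf.tp, conf.fn, conf.fp, conf.tn) == (0, 6, 4, 0)

    def test_matches_direct_tally_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["p", "n"], size=200)
        yhat = rng.choice(["p", "n"], size=200)
        conf = confusion(y, yhat, positive="p")
        tp = sum(1 for t, h in zip(y, yhat) if t == "p" and h == "p")
        fn = sum(1 for t, h in zip(y, yhat) if t == "p" and h == "n")
        fp = sum(1 for t, h in zip(y, yhat) if t == "n" and h == "p")
        tn = sum(1 for t, h in zip(y, yhat) if t == "n" and h == "n")
        assert (conf.tp, conf.fn, conf.fp, conf.tn) == (tp, fn, fp, tn)

    def test_unseen_prediction_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["p", "n"], ["p", "x"], positive="p")


class TestMetrics:
    def test_toy_confusion_hand_computed(self):
        conf = ConfusionMatrix(tp=9, fn=1, fp=2, tn=8, positive="p")
        rep = metrics(conf)
        assert rep.accuracy == 0.85
        assert rep.sensitivity == 0.9
        assert rep.specificity == 0.8
        assert rep.precision == 9 / 11
        expect_f1 = 2 * (9 / 11) * 0.9 / (9 / 11 + 0.9)
        assert abs(rep.f1 - expect_f1) < 1e-15
        assert rep.recall == rep.sensitivity

    def test_single_class_truth_marks_undefined(self):
        # all-negative truth: sensitivity and precision have no meaning
        conf = confusion(["n"] * 5, ["n"] * 5, positive="p")
        rep = metrics(conf)
        assert rep.accuracy == 1.0
        assert rep.sensitivity is None
        assert rep.precision is None
        assert rep.f1 is None
        assert rep.specificity == 1.0

    def test_identities_match_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(0, 20, size=4)
            if tp + fn + fp + tn == 0:
                continue
            rep = metrics(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            assert rep.accuracy == (tp + tn) / (tp + fn + fp + tn)
            if tp + fn:
                assert rep.sensitivity == tp / (tp + fn)
            if tn + fp:
                assert rep.specificity == tn / (tn + fp)
            if tp + fp:
                assert rep.precision == tp / (tp + fp)


class TestAUC:
    def test_perfect_separation(self):
        y = ["p"] * 5 + ["n"] * 5
        s = [0.9, 0.8, 0.95, 0.85, 0.7, 0.1, 0.2, 0.3, 0.15, 0.05]
        auc, lo, hi = auc_with_ci(y, s, "p", n_boot=100, seed=0)
        assert auc == 1.0 and lo == 1.0 and hi == 1.0

    def test_all_tied_scores_half(self):
        y = ["p"] * 4 + ["n"] * 6
        assert auc_mann_whitney(y, [0.5] * 10, "p") == 0.5

    def test_single_class_undefined(self):
        auc, lo, hi = auc_with_ci(["p"] * 5, [0.1] * 5, "p")
        assert auc is None and lo is None and hi is None

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 30
            y = rng.choice(["p", "n"], size=n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # force some ties
            auc = auc_mann_whitney(y, s, "p")
            pos = s[y == "p"]
            neg = s[y == "n"]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert abs(auc - wins / (len(pos) * len(neg))) < 1e-12

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        y = rng.choice([0, 1], size=100)
        s = rng.normal(size=100) + y
        assert abs(auc_mann_whitney(y, s, 1) - roc_auc_score(y, s)) < 1e-12

    def test_bootstrap_ci_reproducible(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["p", "n"], size=60)
        s = rng.normal(size=60)
        a = auc_with_ci(y, s, "p", n_boot=200, seed=9)
        b = auc_with_ci(y, s, "p", n_boot=200, seed=9)
        assert a == b
        c = auc_with_ci(y, s, "p", n_boot=200, seed=10)
        assert a[1:] != c[1:]


def _subject_slices(counts, slices_per_subject=1, strata=None):
    """Build a SliceSet with `counts[label]` subjects per class."""
    recs = []
    for lbl, n in counts.items():
        for i in range(n):
            sid = f"{lbl}{i:04d}"
            stratum = None
            if strata:
                stratum = strata[lbl][i]
            for k in range(slices_per_subject):
                recs.append(SliceRecord(np.zeros((2, 2)), sid, k, label=lbl,
                                        stratum=stratum))
    return SliceSet(recs)


class TestOversample:
    def test_imbalanced_subject_counts_equalized(self):
        data = _subject_slices({"sMCI": 321, "pMCI": 146})
        out = oversample(data, seed=0)
        labels = [out.subject_label(s) for s in out.subject_ids]
        assert labels.count("sMCI") == 321
        assert labels.count("pMCI") == 321

    def test_balanced_input_unchanged(self):
        data = _subject_slices({"a": 10, "b": 10})
        out = oversample(data, seed=0)
        assert len(out) == len(data)

    def test_originals_all_retained(self):
        data = _subject_slices({"a": 9, "b": 3}, slices_per_subject=2)
        out = oversample(data, seed=1)
        original = {(r.subject_id, r.slice_index) for r in data}
        kept = {(r.subject_id, r.slice_index) for r in out}
        assert original <= kept

    def test_whole_subject_duplication(self):
        data = _subject_slices({"a": 5, "b": 2}, slices_per_subject=4)
        out = oversample(data, seed=2)
        for sid in out.subject_ids:
            assert len(out.for_subject(sid)) == 4
        labels = [out.subject_label(s) for s in out.subject_ids]
        assert labels.count("a") == labels.count("b") == 5

    def test_per_stratum_balancing_matches_counting_oracle(self):
        strata = {"a": ["F"] * 9 + ["M"] * 6, "b": ["F"] * 1 + ["M"] * 4}
        data = _subject_slices({"a": 15, "b": 5}, strata=strata)
        out = oversample(data, by_stratum=True, seed=3)
        counts = {}
        for sid in out.subject_ids:
            rec = next(iter(out.for_subject(sid)))
            key = (rec.stratum, rec.label)
            counts[key] = counts.get(key, 0) + 1
        # each stratum balanced independently: F had 9:1, M had 6:4
        assert counts[("F", "a")] == counts[("F", "b")] == 9
        assert counts[("M", "a")] == counts[("M", "b")] == 6

    def test_single_class_stratum_left_unchanged(self):
        strata = {"a": ["F"] * 3 + ["M"] * 3, "b": ["M"] * 3}
        data = _subject_slices({"a": 6, "b": 3}, strata=strata)
        out = oversample(data, by_stratum=True, seed=0)
        f_subjects = [s for s in out.subject_ids
                      if next(iter(out.for_subject(s))).stratum == "F"]
        assert len(f_subjects) == 3  # untouched

    def test_deterministic_under_seed(self):
        data = _subject_slices({"a": 7, "b": 3})
        a = oversample(data, seed=5)
        b = oversample(data, seed=5)
        assert [r.subject_id for r in a] == [r.subject_id for r in b]

    def test_feature_matrix_rows_balanced(self):
        fm = FeatureMatrix(np.arange(20).reshape(10, 2),
                           [f"s{i}:0" for i in range(10)],
                           ["a"] * 7 + ["b"] * 3)
        out = oversample(fm, seed=0)
        assert out.labels.count("a") == out.labels.count("b") == 7


class TestStratifiedSummary:
    def test_single_report_sd_zero(self):
        rep = evaluate_predictions(["p", "n"], ["p", "n"], "p")
        df = stratified_summary([rep])
        row = df[df["group"] == "all"].iloc[0]
        assert row["accuracy_mean"] == 1.0
        assert row["accuracy_sd"] == 0.0

    def test_two_identical_reports_sd_zero(self):
        rep = evaluate_predictions(["p", "n", "p"], ["p", "n", "n"], "p")
        df = stratified_summary([rep, rep])
        assert df[df["group"] == "all"].iloc[0]["accuracy_sd"] == 0.0

    def test_matches_direct_computation_oracle(self):
        rng = np.random.default_rng(6)
        reps = []
        for fold in range(5):
            y = rng.choice(["p", "n"], size=30)
            yhat = rng.choice(["p", "n"], size=30)
            reps.append(evaluate_predictions(y, yhat, "p", fold=fold))
        df = stratified_summary(reps, group_by="fold")
        accs = [r.accuracy for r in reps]
        row = df[df["group"] == "all"].iloc[0]
        assert abs(row["accuracy_mean"] - np.mean(accs)) < 1e-12
        assert abs(row["accuracy_sd"] - np.std(accs)) < 1e-12
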