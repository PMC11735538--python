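"""LOSO logistic classification: fitting, ROC, importance, subset search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from speechling import (
    SubjectRecord,
    classify_pair,
    feature_importance,
    feature_subset_search,
    loso_probabilities,
    roc_auc,
    sens_spec,
    zscore_fit_apply,
)
from speechling.sensitivity import fit_logistic, positive_class, roc_curve_points


def auc_oracle(scores, labels):
    """All-pairs Mann-Whitney comparison."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def two_gaussians(rng, n_per_class=20, delta=4.0, d=2):
    X = np.vstack([
        rng.normal(0, 1, (n_per_class, d)),
        rng.normal(delta, 1, (n_per_class, d)),
    ])
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestZscore:
    def test_train_standardized_to_unit(self, rng):
        X = rng.normal(5, 3, (20, 4))
        tr, te = zscore_fit_apply(X, X)
        assert np.allclose(tr.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(tr.std(axis=0), 1, atol=1e-12)
        assert np.allclose(tr, te)

    def test_constant_feature_named_in_error(self, rng):
        X = rng.normal(0, 1, (10, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="mattr"):
            zscore_fit_apply(X, X, ["mlu", "mattr", "ngram_repetition"])

    def test_test_shift_scales_by_train_sd(self, rng):
        X = rng.normal(0, 2, (30, 1))
        sd = X.std(axis=0)
        _, te1 = zscore_fit_apply(X, X[:5])
        _, te2 = zscore_fit_apply(X, X[:5] + 3.0)
        assert np.allclose(te2 - te1, 3.0 / sd)


class TestLogisticFit:
    def test_matches_sklearn_at_same_ridge(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = two_gaussians(rng, n_per_class=30, delta=1.5, d=3)
        ridge = 1.0  # appreciable penalty so both solvers are well-conditioned
        w = fit_logistic(X, y, ridge=ridge)
        ref = sklearn.LogisticRegression(
            C=1.0 / ridge, solver="lbfgs", max_iter=5000, tol=1e-12
        ).fit(X, y)
        assert w[0] == pytest.approx(ref.intercept_[0], abs=1e-4)
        assert np.allclose(w[1:], ref.coef_[0], atol=1e-4)

    def test_separable_data_stays_finite(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.repeat([0, 1], 10)
        w = fit_logistic(X, y, ridge=1e-4)
        assert np.all(np.isfinite(w))


class TestLoso:
    def test_well_separated_classes_all_correct(self):
        # high-probability event at this separation; seed fixed accordingly
        rng = np.random.default_rng(7)
        X, y = two_gaussians(rng, n_per_class=20, delta=4.0)
        probs = loso_probabilities(X, y)
        assert np.all((probs.to_numpy() > 0.5) == (y == 1))

    def test_matches_explicit_single_fold(self, rng):
        # independent re-derivation of one held-out probability
        from scipy.special import expit

        X, y = two_gaussians(rng, n_per_class=8, delta=1.0)
        probs = loso_probabilities(X, y)
        i = 5
        mask = np.ones(len(y), bool)
        mask[i] = False
        Xtr, Xte = zscore_fit_apply(X[mask], X[[i]])
        w = fit_logistic(Xtr, y[mask])
        assert probs.iloc[i] == pytest.approx(float(expit(w[0] + Xte[0] @ w[1:])), abs=1e-12)

    def test_outside_fold_scaling_option(self, rng):
        # global scaling is a replication option; on already-standardized
        # data it must coincide with the default in-fold scaling only up to
        # the fold-mean shifts, and always returns valid probabilities
        X, y = two_gaussians(rng, n_per_class=10, delta=2.0)
        p_out = loso_probabilities(X, y, scale_outside_folds=True)
        assert ((p_out >= 0) & (p_out <= 1)).all()
        p_in = loso_probabilities(X, y)
        assert not np.allclose(p_in, p_out)  # genuinely different procedures

    def test_fold_losing_a_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError, match="lose a class"):
            loso_probabilities(X, y)

    def test_duplicated_feature_column_nearly_no_effect(self, rng):
        X, y = two_gaussians(rng, n_per_class=15, delta=2.0, d=2)
        p1 = loso_probabilities(X, y)
        p2 = loso_probabilities(np.hstack([X, X[:, [0]]]), y)
        # ridge splits the duplicated coefficient; probabilities move only by
        # the (tiny) difference in effective penalty
        assert np.max(np.abs(p1.to_numpy() - p2.to_numpy())) < 0.01

    def test_no_leakage_from_held_out_subject(self, rng):
        # corrupting subject i's features must not move anyone's training
        # fold: every other subject's model sees the corruption, but subject
        # i's own probability must derive from a model that never saw row i
        X, y = two_gaussians(rng, n_per_class=10, delta=2.0)
        i = 3
        X_wild = X.copy()
        X_wild[i] = 1e6  # absurd outlier
        mask = np.ones(len(y), bool)
        mask[i] = False
        probs_wild = loso_probabilities(X_wild, y)
        # re-derive subject i's fold from the uncorrupted training rows
        Xtr, Xte = zscore_fit_apply(X_wild[mask], X_wild[[i]])
        from scipy.special import expit

        w = fit_logistic(Xtr, y[mask])
        assert probs_wild.iloc[i] == pytest.approx(
            float(expit(w[0] + Xte[0] @ w[1:])), abs=1e-12
        )
        assert np.allclose(Xtr, zscore_fit_apply(X[mask], X[[i]])[0])

    def test_label_permutation_auc_near_half_with_pessimistic_bias(self, rng):
        # pooled LOSO probabilities are slightly anti-ranked under the null:
        # each training fold's class balance tilts against the held-out
        # subject (the leave-one-out majority-classifier pathology), so the
        # permutation-null AUC sits somewhat BELOW 0.5 rather than on it
        n = 30
        X = rng.normal(0, 1, (n, 3))
        aucs = []
        for _ in range(80):
            y = rng.permutation(np.repeat([0, 1], n // 2))
            aucs.append(roc_auc(loso_probabilities(X, y), y))
        mean = np.mean(aucs)
        assert 0.30 < mean < 0.52
        assert mean < 0.5 + 0.03  # never optimistically biased


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_all_pairs_oracle_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.2, 0.5, 0.8], n)
            assert roc_auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_roc_curve_starts_and_ends_at_corners(self, rng):
        pts = roc_curve_points(rng.random(20), rng.integers(0, 2, 20) | np.arange(20) % 2)
        assert pts.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert pts.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]


class TestSensSpec:
    def test_perfect_separation(self):
        s, sp = sens_spec([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (s, sp) == (1.0, 1.0)

    def test_all_predicted_positive(self):
        s, sp = sens_spec([0.9, 0.9, 0.9, 0.9], [0, 1, 0, 1], threshold=0.5)
        assert (s, sp) == (1.0, 0.0)

    def test_sensitivity_monotone_in_threshold(self, rng):
        p = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        sens = [sens_spec(p, y, threshold=t)[0] for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestImportance:
    def test_informative_feature_dominates(self, rng):
        n = 60
        informative = np.repeat([0.0, 3.0], n // 2) + rng.normal(0, 1, n)
        noise = rng.normal(0, 1, (n, 3))
        X = pd.DataFrame(
            np.column_stack([informative, noise]),
            columns=["mlu", "mattr", "ngram_repetition", "content_words"],
        )
        y = np.repeat([0, 1], n // 2)
        imp = feature_importance(X, y, ridge=1.0)
        assert imp.index[0] == "mlu"
        assert imp.iloc[0] > 3 * imp.iloc[1]

    def test_invariant_to_raw_feature_rescaling(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
        y = (X["a"] + rng.normal(0, 1, n) > 0).astype(int)
        imp1 = feature_importance(X, y)
        X2 = X.copy()
        X2["b"] = X2["b"] * 1000.0
        imp2 = feature_importance(X2, y)
        assert np.allclose(imp1.sort_index(), imp2.sort_index(), atol=1e-8)

    def test_symmetric_features_equally_important(self, rng):
        n = 400
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        logit = 1.2 * (a + b)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        imp = feature_importance(pd.DataFrame({"a": a, "b": b}), y, ridge=1.0)
        assert imp["a"] == pytest.approx(imp["b"], rel=0.25)


def make_pair_records(n_per_group, groups=("PD", "MSA")):
    recs = []
    for g in groups:
        for i in range(n_per_group):
            recs.append(SubjectRecord(f"{g}{i:03d}", g, 60.0, "M", "hobby"))
    return recs


class TestPairClassification:
    def test_positive_class_is_more_affected(self):
        assert positive_class(("HC", "PD")) == "PD"
        assert positive_class(("HC", "MSA")) == "MSA"
        assert positive_class(("MSA", "PD")) == "MSA"

    def _features(self, rng, n=16, shift=3.0):
        recs = make_pair_records(n)
        rows = []
        for r in recs:
            mu = shift if r.group == "MSA" else 0.0
            rows.append(rng.normal(mu, 1, 2))
        feats = pd.DataFrame(
            rows, index=[r.subject_id for r in recs], columns=["mlu", "mattr"]
        )
        return feats, recs

    def test_classify_pair_reports_all_fields(self, rng):
        feats, recs = self._features(rng)
        res = classify_pair(feats, recs, pair=("PD", "MSA"), feature_subset=["mlu", "mattr"])
        assert res.positive == "MSA"
        assert res.auc > 0.9
        assert 0 <= res.sensitivity <= 1 and 0 <= res.specificity <= 1
        assert set(res.importance.index) == {"mlu", "mattr"}
        assert len(res.probabilities) == 32

    def test_subset_search_finds_informative_feature(self, rng):
        recs = make_pair_records(14)
        n = len(recs)
        informative = np.array([3.0 if r.group == "MSA" else 0.0 for r in recs])
        feats = pd.DataFrame(
            {
                "mlu": informative + rng.normal(0, 1, n),
                "mattr": rng.normal(0, 1, n),
                "ngram_repetition": rng.normal(0, 1, n),
            },
            index=[r.subject_id for r in recs],
        )
        best, result, log = feature_subset_search(
            feats, recs, pair=("PD", "MSA"),
            candidates=["mlu", "mattr", "ngram_repetition"],
        )
        assert "mlu" in best
        assert log.shape[0] == 7  # 2^3 - 1 subsets
        # the winner's AUC matches the exhaustive maximum by definition
        assert result.auc == pytest.approx(log["auc"].max())

    def test_subset_search_deterministic(self, rng):
        feats, recs = self._features(rng, n=10, shift=1.0)
        a = feature_subset_search(feats, recs, pair=("PD", "MSA"))
        b = feature_subset_search(feats, recs, pair=("PD", "MSA"))
        assert a[0] == b[0]
        assert a[1].auc == b[1].auc
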