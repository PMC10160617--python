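"""Classification tests: CV contracts, fast LDA paths, voting, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from maldi_tma import (
    CohortClassifier,
    CVScheme,
    accuracy_from_counts,
    cross_validate,
    f1_from_counts,
    majority_vote,
    max_class_guess,
    random_weighted_guess,
)
from maldi_tma.classify import _logo_lda_predictions, _loocv_lda_predictions
from maldi_tma.preprocess import FeatureMatrix


def _gaussian_fm(rng, n=60, p=8, sep=6.0, ids=None):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p))
    X[y == 1, 0] += sep
    ids = ids or [f"u{i}" for i in range(n)]
    fm = FeatureMatrix(X, np.linspace(700, 800, p), pd.Index(ids), "patient")
    return fm, y


class TestFastLdaPaths:
    def test_loocv_fast_path_matches_naive_sklearn_loop(self):
        rng = np.random.default_rng(0)
        fm, y = _gaussian_fm(rng, n=50, p=7, sep=1.0)
        fast = _loocv_lda_predictions(fm.values, y)
        naive = np.empty_like(fast)
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            clf = LinearDiscriminantAnalysis(solver="svd").fit(fm.values[tr], y[tr])
            naive[i] = clf.predict(fm.values[i : i + 1])[0]
        assert np.array_equal(fast, naive)

    def test_leave_one_patient_out_matches_naive_sklearn_loop(self):
        rng = np.random.default_rng(1)
        n_pat, m, p = 24, 3, 10
        t = np.repeat(rng.normal(0, 1, n_pat) + np.repeat([0.8, -0.8], n_pat // 2), m)
        X = t[:, None] * rng.normal(0.5, 0.1, p)[None, :] + rng.normal(0, 1, (n_pat * m, p))
        y = np.repeat([1] * (n_pat // 2) + [0] * (n_pat // 2), m)
        groups = np.repeat(np.arange(n_pat), m)
        fast = _logo_lda_predictions(X, y, groups)
        naive = np.empty_like(fast)
        for g in range(n_pat):
            te = groups == g
            clf = LinearDiscriminantAnalysis(solver="svd").fit(X[~te], y[~te])
            naive[te] = clf.predict(X[te])
        assert np.array_equal(fast, naive)


class TestCrossValidate:
    def test_separable_classes_near_perfect(self):
        rng = np.random.default_rng(2)
        fm, y = _gaussian_fm(rng, sep=8.0)
        report, _ = cross_validate(fm, y, "lda", CVScheme("loocv"))
        assert report.accuracy > 0.97

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(3)
        fm, y = _gaussian_fm(rng, n=200, p=5, sep=3.0)
        y_perm = rng.permutation(y)
        report, _ = cross_validate(fm, y_perm, "lda", CVScheme("kfold", k=10, seed=0))
        assert 0.35 <= report.accuracy <= 0.65

    def test_same_seed_identical_report(self, small_fm_pat, small_labels):
        r1, p1 = cross_validate(small_fm_pat, small_labels, "lda", CVScheme("kfold", k=5, seed=4))
        r2, p2 = cross_validate(small_fm_pat, small_labels, "lda", CVScheme("kfold", k=5, seed=4))
        assert p1.equals(p2)
        assert r1.as_dict() == r2.as_dict()

    def test_every_unit_predicted_once(self, small_fm_pat, small_labels):
        _, preds = cross_validate(small_fm_pat, small_labels, "lda", CVScheme("kfold", k=5, seed=0))
        assert preds.index.equals(small_fm_pat.unit_ids)
        assert preds.notna().all()

    def test_kfold_partitions_exactly_and_respects_patients(self, small_fm_syn, small_cohort):
        _, meta = small_cohort
        y = meta.patients.loc[small_fm_syn.units["patient_id"], "group"].to_numpy()
        scheme = CVScheme("kfold", k=5, group_by_patient=True, seed=1)
        groups = small_fm_syn.units["patient_id"].to_numpy()
        folds = list(scheme.split(small_fm_syn.values, y, groups))
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(small_fm_syn.n_units))
        fold_of = np.empty(small_fm_syn.n_units, dtype=int)
        for f, (_, te) in enumerate(folds):
            fold_of[te] = f
        for g in pd.unique(groups):
            assert len(set(fold_of[groups == g])) == 1

    def test_too_few_units_per_class_rejected(self):
        rng = np.random.default_rng(5)
        fm, _ = _gaussian_fm(rng, n=10, p=3)
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="2 units per class"):
            cross_validate(fm, y, "lda", CVScheme("loocv"))

    def test_nested_auroc_selection_reports_feature_count(self, small_fm_pat, small_cohort, small_labels):
        report, _ = cross_validate(
            small_fm_pat,
            small_labels,
            "lda",
            CVScheme("kfold", k=5, seed=0),
            feature_selector=("auroc", 0.7),
        )
        assert 0 < report.n_features < small_fm_pat.n_features


class TestMajorityVote:
    def _units(self, assignments):
        return pd.DataFrame(
            {"patient_id": assignments},
            index=pd.Index([f"s{i}" for i in range(len(assignments))]),
        )

    def test_modal_class_wins(self):
        preds = pd.Series([1, 1, 0], index=["s0", "s1", "s2"])
        out = majority_vote(preds, self._units(["P1", "P1", "P1"]))
        assert out.loc["P1"] == 1

    def test_tie_goes_to_untreated(self):
        preds = pd.Series([1, 0], index=["s0", "s1"])
        out = majority_vote(preds, self._units(["P1", "P1"]))
        assert out.loc["P1"] == 0

    def test_vote_lift_matches_binomial_oracle(self):
        """With conditionally independent per-spectrum accuracy p > 0.5
        over m spectra, patient accuracy follows the binomial tail (ties
        to class 0), and exceeds p."""
        rng = np.random.default_rng(8)
        p_spec, m, n_pat = 0.75, 9, 4000
        truth = rng.integers(0, 2, n_pat)
        correct = rng.random((n_pat, m)) < p_spec
        spec_pred = np.where(correct, truth[:, None], 1 - truth[:, None])
        pat_ids = [f"P{i}" for i in range(n_pat)]
        units = self._units(np.repeat(pat_ids, m))
        preds = pd.Series(spec_pred.ravel(), index=units.index)
        vote = majority_vote(preds, units)
        truth_s = pd.Series(truth, index=pat_ids)
        acc = (vote == truth_s.loc[vote.index]).mean()
        # oracle: odd m, no ties possible -> P(Binom(m, p) > m/2)
        oracle = 1 - binom.cdf(m // 2, m, p_spec)
        assert acc == pytest.approx(oracle, abs=0.02)
        assert acc > p_spec


class TestMetrics:
    def test_accuracy_from_counts_rounding(self):
        assert accuracy_from_counts(138, 161, 103, 128) == 83
        assert accuracy_from_counts(26934, 31932, 26587, 31294) == 85
        assert accuracy_from_counts(0, 10, 0, 5) == 0

    def test_accuracy_invalid_counts(self):
        with pytest.raises(ValueError):
            accuracy_from_counts(1, 0, 1, 5)
        with pytest.raises(ValueError):
            accuracy_from_counts(6, 5, 1, 5)

    def test_f1_bounds_and_conventions(self):
        assert f1_from_counts(10, 10, 5, 5) == 1.0
        assert f1_from_counts(0, 10, 0, 5) == 0.0
        # swapping the positive class changes the value
        a = f1_from_counts(120, 161, 100, 128, positive=0)
        b = f1_from_counts(120, 161, 100, 128, positive=1)
        assert a != pytest.approx(b)

    def test_max_class_guess(self):
        assert max_class_guess([0] * 161 + [1] * 128) == pytest.approx(161 / 289)
        assert max_class_guess([0, 1]) == 0.5
        assert max_class_guess([1, 1, 1]) == 1.0

    def test_random_weighted_guess(self):
        assert random_weighted_guess([0, 1]) == 0.5
        assert random_weighted_guess([1, 1]) == 1.0
        p0, p1 = 161 / 289, 128 / 289
        assert random_weighted_guess([0] * 161 + [1] * 128) == pytest.approx(p0**2 + p1**2)


class TestCohortClassifier:
    def test_models_beat_both_baselines(self, small_cohort, small_fm_pat):
        _, meta = small_cohort
        for model in ("lda", "svm"):
            res = CohortClassifier(
                small_fm_pat, meta, model, CVScheme("kfold", k=5, seed=0)
            ).fit()
            b = res.baselines()
            assert res.accuracy > b["max_class_guess"]
            assert res.accuracy > b["random_weighted_guess"]

    def test_vote_results_present_at_spectrum_level(self, small_cohort, small_fm_syn):
        _, meta = small_cohort
        res = CohortClassifier(
            small_fm_syn,
            meta,
            "lda",
            CVScheme("kfold", k=5, group_by_patient=True, seed=0),
            vote=True,
            shrinkage="diag",
        ).fit()
        assert res.patient_predictions is not None
        assert len(res.patient_predictions) == meta.n_patients
        assert res.report.majority_vote_accuracy is not None
        text = res.summary()
        assert "majority vote" in text and "LpPRP-0" in text
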