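"""LDA/SVM treatment-group classification with cross-validation.

The central objects follow the model/results convention: a
:class:`CohortClassifier` is built from a feature matrix and cohort
metadata, and its :meth:`~CohortClassifier.fit` returns a
:class:`ClassificationResults` carrying per-class counts, accuracy, F1,
optional majority-vote patient accuracy and a printable summary.

Cross-validation schemes are leave-one-out and stratified k-fold (k = 10
by default), at the spectrum or patient level; at the spectrum level an
optional majority vote aggregates per-spectrum predictions into one
prediction per patient (modal class; ties go to LpPRP-0).  Feature
selection (AUROC threshold or forward stepwise) is re-run inside every
training fold so the reported accuracy is free of selection leakage.

Two random-guess baselines calibrate the achieved accuracies: the
maximum-class guess (always predict the most abundant class) and the
random-weighted guess (predict each class with its prior probability,
expected accuracy ``sum_c p_c^2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .cohort import GROUP_NAMES, CohortMeta
from .featstats import (
    ForwardSelectionConfig,
    SelectionConfig,
    feature_stats,
    forward_select,
    select_by_threshold,
)
from .preprocess import FeatureMatrix

__all__ = [
    "CVScheme",
    "ClassificationReport",
    "CohortClassifier",
    "ClassificationResults",
    "cross_validate",
    "majority_vote",
    "f1_from_counts",
    "accuracy_from_counts",
    "max_class_guess",
    "random_weighted_guess",
]


@dataclass
class CVScheme:
    """Cross-validation layout.

    ``group_by_patient`` keeps all spectra of a patient in the same fold
    (only meaningful at the spectrum level).
    """

    kind: str = "loocv"
    k: int = 10
    stratified: bool = True
    group_by_patient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ValueError("kind must be 'loocv' or 'kfold'")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2 for k-fold")

    def split(self, X, y, groups=None):
        """Yield (train_idx, test_idx) pairs forming an exact partition."""
        n = len(y)
        if self.kind == "loocv":
            if self.group_by_patient and groups is not None:
                for g in pd.unique(groups):
                    te = np.flatnonzero(groups == g)
                    tr = np.flatnonzero(groups != g)
                    yield tr, te
            else:
                idx = np.arange(n)
                for i in range(n):
                    yield np.delete(idx, i), np.array([i])
            return
        seed = self.seed % (2**31)
        if self.group_by_patient and groups is not None:
            splitter = StratifiedGroupKFold(n_splits=self.k, shuffle=True, random_state=seed)
            yield from splitter.split(X, y, groups)
        else:
            splitter = StratifiedKFold(n_splits=self.k, shuffle=True, random_state=seed)
            yield from splitter.split(X, y)


@dataclass
class ClassificationReport:
    """Machine analog of one row of a classification-strategies table."""

    model: str
    cv: str
    unit_level: str
    correct: dict[int, int]
    total: dict[int, int]
    f1: float
    n_features: int
    seed: int
    majority_vote_accuracy: float | None = None
    majority_correct: dict[int, int] | None = None
    majority_total: dict[int, int] | None = None

    @property
    def accuracy(self) -> float:
        return sum(self.correct.values()) / sum(self.total.values())

    @property
    def accuracy_pct(self) -> int:
        return accuracy_from_counts(
            self.correct[0], self.total[0], self.correct[1], self.total[1]
        )

    def as_dict(self) -> dict:
        d = {
            "model": self.model,
            "cv": self.cv,
            "unit_level": self.unit_level,
            "correct_0": self.correct[0],
            "total_0": self.total[0],
            "correct_1": self.correct[1],
            "total_1": self.total[1],
            "accuracy_pct": self.accuracy_pct,
            "f1": round(self.f1, 2),
            "n_features": self.n_features,
            "seed": self.seed,
        }
        if self.majority_vote_accuracy is not None:
            d["majority_vote_accuracy_pct"] = _round_half_up(
                100.0 * self.majority_vote_accuracy
            )
        return d


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def accuracy_from_counts(correct_0, total_0, correct_1, total_1) -> int:
    """Overall accuracy as an integer percentage (rounded half up)."""
    if total_0 <= 0 or total_1 <= 0:
        raise ValueError("class totals must be positive")
    if correct_0 > total_0 or correct_1 > total_1:
        raise ValueError("correct counts cannot exceed totals")
    return _round_half_up(100.0 * (correct_0 + correct_1) / (total_0 + total_1))


def f1_from_counts(correct_0, total_0, correct_1, total_1, positive: int = 0) -> float:
    """F1 score from per-class correct/total counts.

    The reported positive label defaults to LpPRP-0 (the convention that
    best reproduces published per-strategy F1 values from their counts;
    switchable via ``positive``).  Returns 0 when nothing is predicted
    positive.
    """
    if total_0 <= 0 or total_1 <= 0:
        raise ValueError("class totals must be positive")
    if positive == 0:
        tp, fn, fp = correct_0, total_0 - correct_0, total_1 - correct_1
    else:
        tp, fn, fp = correct_1, total_1 - correct_1, total_0 - correct_0
    if tp + fp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def max_class_guess(labels) -> float:
    """Expected accuracy of always predicting the most abundant class."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(y, return_counts=True)
    return counts.max() / y.size


def random_weighted_guess(labels) -> float:
    """Expected accuracy of predicting each class with its prior: sum p_c^2."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(np.sum(p**2))


def majority_vote(spectrum_predictions: pd.Series, units: pd.DataFrame) -> pd.Series:
    """Aggregate per-spectrum predictions to one prediction per patient.

    The patient label is the modal spectrum prediction; exact ties go to
    LpPRP-0 (class 0).  ``units`` must map each spectrum to its
    ``patient_id``.
    """
    pids = units.loc[spectrum_predictions.index, "patient_id"]
    if pids.isna().any():
        raise ValueError("every spectrum must map to a patient")
    votes = spectrum_predictions.groupby(pids.to_numpy()).mean()
    out = (votes > 0.5).astype(int)  # tie (exactly 0.5) -> class 0
    out.index.name = "patient_id"
    return out


# ---------------------------------------------------------------------------
# estimators


class DiagonalLDA:
    """Gaussian LDA with a diagonal pooled covariance (naive-Bayes LDA).

    In the p > n_effective regime — spectrum-level data where the spectra
    of one patient are correlated, so the number of independent units is
    the number of patients — estimating the full pooled covariance adds
    more noise than signal, and the diagonal estimator is the robust
    classical choice.  Priors are the training class frequencies.
    """

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        self.m0_ = X[y == 0].mean(axis=0)
        self.m1_ = X[y == 1].mean(axis=0)
        Xc = X - np.where(y[:, None] == 0, self.m0_, self.m1_)
        var = (Xc**2).sum(axis=0) / max(len(y) - 2, 1)
        self.var_ = np.maximum(var, np.finfo(float).tiny)
        n1 = int(y.sum())
        self.bias_ = math.log(n1 / (len(y) - n1))
        self.w_ = (self.m1_ - self.m0_) / self.var_
        return self

    def predict(self, X):
        scores = X @ self.w_ - 0.5 * self.w_ @ (self.m0_ + self.m1_) + self.bias_
        return (scores > 0).astype(int)


def _make_estimator(model: str, n_train: int, n_features: int, shrinkage: str | None = None):
    model = model.lower()
    if model == "lda":
        if shrinkage == "diag":
            return DiagonalLDA()
        if shrinkage == "lw" or n_features >= n_train:
            # Ledoit-Wolf shrinkage: mandatory when the pooled covariance
            # is singular, opt-in when spectra within a patient are
            # correlated and the nominal sample size overstates the
            # covariance information
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis(solver="svd")
    if model == "svm":
        # TIC-normalized intensities are tiny (~1/n_bins); the linear SVM
        # needs unit-variance features for C=1 to be a sensible scale
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    raise ValueError(f"unknown model {model!r}; expected 'lda' or 'svm'")


def _loocv_lda_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact leave-one-out LDA predictions via rank-one downdates.

    Refitting LDA n times is O(n * p^3); this path updates the inverse
    pooled scatter with the Sherman-Morrison identity so each held-out
    prediction costs O(p^2).  Numerically it reproduces a naive
    retrain-per-sample loop (verified in the test suite).  Requires
    p < n - 2 so the pooled scatter is invertible.
    """
    n, p = X.shape
    classes = np.unique(y)
    if set(classes) != {0, 1}:
        raise ValueError("fast LOOCV path expects binary 0/1 labels")
    n0 = int((y == 0).sum())
    n1 = n - n0
    if min(n0, n1) < 2:
        raise ValueError("need >= 2 units per class")
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    Xc = X - np.where(y[:, None] == 0, m0, m1)
    S = Xc.T @ Xc
    S.flat[:: p + 1] += 1e-10 * np.trace(S) / p
    Sinv = np.linalg.inv(S)

    preds = np.empty(n, dtype=int)
    for i in range(n):
        x = X[i]
        c = int(y[i])
        if c == 0:
            nc, mc = n0, m0
            m0p = (n0 * m0 - x) / (n0 - 1)
            m1p = m1
            n0p, n1p = n0 - 1, n1
        else:
            nc, mc = n1, m1
            m1p = (n1 * m1 - x) / (n1 - 1)
            m0p = m0
            n0p, n1p = n0, n1 - 1
        alpha = nc / (nc - 1)
        d = x - mc
        Sd = Sinv @ d
        denom = 1.0 - alpha * (d @ Sd)
        v = m1p - m0p
        Sv = Sinv @ v
        # (S - alpha d d^T)^{-1} v  via Sherman-Morrison
        Sinv_v = Sv + alpha * Sd * (d @ Sv) / denom
        w = ((n - 1) - 2) * Sinv_v  # scatter -> pooled covariance scale
        score = w @ x - 0.5 * w @ (m0p + m1p) + math.log(n1p / n0p)
        preds[i] = 1 if score > 0 else 0
    return preds


def _logo_lda_predictions(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Exact leave-one-patient-out LDA predictions via Woodbury downdates.

    All spectra of one patient are held out together (one class per
    patient).  Removing the block R of m same-class samples changes the
    pooled scatter by the rank-(m+2) symmetric term

        S' = S - X_R^T X_R + n_c m_c m_c^T - n_c' m_c' m_c'^T,

    so ``S'^{-1} v`` costs O(p^2 (m+2)) through the Woodbury identity
    instead of a fresh O(p^3) factorization per patient.  Matches a naive
    retrain-per-patient loop (verified in the test suite).
    """
    n, p = X.shape
    n0 = int((y == 0).sum())
    n1 = n - n0
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    Xc = X - np.where(y[:, None] == 0, m0, m1)
    S = Xc.T @ Xc
    S.flat[:: p + 1] += 1e-10 * np.trace(S) / p
    Sinv = np.linalg.inv(S)

    preds = np.empty(n, dtype=int)
    for g in pd.unique(groups):
        te = np.flatnonzero(groups == g)
        c = int(y[te[0]])
        if not np.all(y[te] == c):
            raise ValueError("a patient's spectra must share one label")
        XR = X[te]
        m = len(te)
        if c == 0:
            nc, mc = n0, m0
            mcp = (n0 * m0 - XR.sum(axis=0)) / (n0 - m)
            m0p, m1p = mcp, m1
            n0p, n1p = n0 - m, n1
        else:
            nc, mc = n1, m1
            mcp = (n1 * m1 - XR.sum(axis=0)) / (n1 - m)
            m0p, m1p = m0, mcp
            n0p, n1p = n0, n1 - m
        if min(n0p, n1p) < 2:
            raise ValueError("need >= 2 spectra per class after holding out a patient")
        # S' = S - U C U^T with U = [X_R^T, m_c, m_c'], C = diag(1..1, -n_c, n_c')
        U = np.concatenate([XR, mc[None, :], mcp[None, :]], axis=0).T  # p x (m+2)
        cdiag = np.concatenate([np.ones(m), [-float(nc), float(nc - m)]])
        SiU = Sinv @ U
        K = np.diag(1.0 / cdiag) - U.T @ SiU
        v = m1p - m0p
        Siv = Sinv @ v
        # S'^{-1} v = Sinv v + SiU K^{-1} SiU^T v   (Woodbury)
        Sinv_v = Siv + SiU @ np.linalg.solve(K, SiU.T @ v)
        w = ((n - m) - 2) * Sinv_v
        scores = XR @ w - 0.5 * w @ (m0p + m1p) + math.log(n1p / n0p)
        preds[te] = (scores > 0).astype(int)
    return preds


def _select_features(fm: FeatureMatrix, y: np.ndarray, selector, model: str):
    """Apply a feature-selection rule on (training) data; returns mz list."""
    if selector is None:
        return None
    kind = selector[0]
    if kind == "auroc":
        cfg = selector[1] if isinstance(selector[1], SelectionConfig) else SelectionConfig(
            auroc_threshold=float(selector[1])
        )
        stats = feature_stats(fm, y)
        return select_by_threshold(stats, cfg)
    if kind == "forward":
        cfg = selector[1] if len(selector) > 1 else ForwardSelectionConfig()
        mzs, _ = forward_select(fm, y, model=model, cfg=cfg)
        return mzs
    raise ValueError(f"unknown feature selector {selector!r}")


def cross_validate(
    fm: FeatureMatrix,
    labels,
    model: str = "lda",
    scheme: CVScheme | None = None,
    feature_selector=None,
    shrinkage: str | None = None,
) -> tuple[ClassificationReport, pd.Series]:
    """Out-of-fold predictions for every unit, plus the summary report.

    Every unit is predicted exactly once by a model never trained on it
    (nor on any unit of the same patient when the scheme groups by
    patient).  ``feature_selector`` — ``("auroc", threshold_or_config)``
    or ``("forward", config)`` — is re-applied inside each training fold.
    """
    scheme = scheme or CVScheme()
    y = np.asarray(labels, dtype=int)
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 units per class")
    groups = None
    if fm.units is not None and "patient_id" in fm.units.columns:
        groups = fm.units["patient_id"].to_numpy()

    n_feat_used = fm.n_features
    preds = pd.Series(index=fm.unit_ids, dtype=float, name="prediction")

    grouped = scheme.group_by_patient and groups is not None and pd.notna(groups).all()
    fast_ok = (
        model.lower() == "lda"
        and scheme.kind == "loocv"
        and feature_selector is None
        and shrinkage is None
        and fm.n_features < fm.n_units - 2
    )
    if fast_ok and not grouped:
        preds[:] = _loocv_lda_predictions(fm.values, y)
    elif (
        fast_ok
        and grouped
        and fm.n_features < fm.n_units - fm.units["patient_id"].value_counts().max() - 2
    ):
        preds[:] = _logo_lda_predictions(fm.values, y, np.asarray(groups))
    else:
        folds = list(scheme.split(fm.values, y, groups))
        _check_partition(folds, fm.n_units, groups if scheme.group_by_patient else None)
        selected_sizes = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                raise ValueError(
                    "a training fold lost one class entirely; use a stratified scheme"
                )
            if feature_selector is not None:
                sub = fm.subset_units(np.isin(np.arange(fm.n_units), tr))
                mzs = _select_features(sub, y[tr], feature_selector, model)
                if not mzs:
                    raise ValueError("feature selector returned no features in a fold")
                Xtr = sub.subset_features(mzs).values
                cols = np.searchsorted(fm.mz_bins, sorted(mzs))
                Xte = fm.values[te][:, cols]
                selected_sizes.append(len(mzs))
            else:
                Xtr = fm.values[tr]
                Xte = fm.values[te]
            est = _make_estimator(model, len(tr), Xtr.shape[1], shrinkage)
            est.fit(Xtr, y[tr])
            preds.iloc[te] = est.predict(Xte)
        if selected_sizes:
            n_feat_used = int(round(float(np.mean(selected_sizes))))

    preds = preds.astype(int)
    correct = {c: int(((preds.to_numpy() == y) & (y == c)).sum()) for c in (0, 1)}
    total = {c: int((y == c).sum()) for c in (0, 1)}
    report = ClassificationReport(
        model=model.upper(),
        cv=scheme.kind,
        unit_level=fm.unit_level,
        correct=correct,
        total=total,
        f1=f1_from_counts(correct[0], total[0], correct[1], total[1]),
        n_features=n_feat_used,
        seed=scheme.seed,
    )
    return report, preds


def _check_partition(folds, n, groups=None) -> None:
    seen = np.concatenate([te for _, te in folds])
    if len(seen) != n or len(np.unique(seen)) != n:
        raise AssertionError("cross-validation folds must partition the units exactly")
    if groups is not None:
        fold_of = np.empty(n, dtype=int)
        for f, (_, te) in enumerate(folds):
            fold_of[te] = f
        for g in pd.unique(groups):
            if len(np.unique(fold_of[groups == g])) != 1:
                raise AssertionError(f"patient {g} spans multiple folds")


# ---------------------------------------------------------------------------
# model / results


class CohortClassifier:
    """Treatment-group discrimination model over a cohort feature matrix.

    Parameters
    ----------
    fm : FeatureMatrix
        Spectrum- or patient-level matrix with lineage metadata.
    meta : CohortMeta
        Supplies group labels (and the spectrum -> patient map for
        majority voting).
    model : {"lda", "svm"}
    scheme : CVScheme
    feature_selector : None, ("auroc", threshold or SelectionConfig), or
        ("forward", ForwardSelectionConfig); re-fit inside each training
        fold.
    vote : bool
        At the spectrum level, also aggregate predictions per patient by
        majority vote.

    Examples
    --------
    >>> model = CohortClassifier(fm_patients, meta, model="lda",
    ...                          scheme=CVScheme("kfold", k=10, seed=0))
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(
        self,
        fm: FeatureMatrix,
        meta: CohortMeta,
        model: str = "lda",
        scheme: CVScheme | None = None,
        feature_selector=None,
        vote: bool = False,
        shrinkage: str | None = None,
    ):
        self.fm = fm
        self.meta = meta
        self.model = model
        self.scheme = scheme or CVScheme()
        self.feature_selector = feature_selector
        self.vote = vote and fm.unit_level == "spectrum"
        self.shrinkage = shrinkage
        self.labels = self._resolve_labels()

    @classmethod
    def from_spectra(cls, sset, meta, bin_width: float = 0.5, level: str = "patient", **kw):
        """Build directly from a SpectrumSet: normalize, bin, mask, average."""
        from .preprocess import align_masses, filter_annotated, patient_mean_spectra, tic_normalize

        fm = filter_annotated(align_masses(tic_normalize(sset), bin_width), meta)
        if level == "patient":
            fm = patient_mean_spectra(fm, meta)
        return cls(fm, meta, **kw)

    def _resolve_labels(self) -> np.ndarray:
        if self.fm.unit_level == "patient":
            return self.meta.labels_for(self.fm.unit_ids).to_numpy()
        pids = self.fm.units["patient_id"]
        if pids.isna().any():
            raise ValueError("spectrum-level classification requires patient lineage")
        return self.meta.patients.loc[pids, "group"].to_numpy()

    def fit(self) -> "ClassificationResults":
        report, preds = cross_validate(
            self.fm, self.labels, self.model, self.scheme, self.feature_selector, self.shrinkage
        )
        patient_preds = None
        if self.vote:
            patient_preds = majority_vote(preds, self.fm.units)
            truth = self.meta.labels_for(patient_preds.index)
            mc = {
                c: int(((patient_preds == truth) & (truth == c)).sum()) for c in (0, 1)
            }
            mt = {c: int((truth == c).sum()) for c in (0, 1)}
            report.majority_correct = mc
            report.majority_total = mt
            report.majority_vote_accuracy = sum(mc.values()) / sum(mt.values())
        return ClassificationResults(self, report, preds, patient_preds)


class ClassificationResults:
    """Fitted cross-validated classification outcome."""

    def __init__(self, model, report, predictions, patient_predictions=None):
        self.model = model
        self.report = report
        self.predictions = predictions
        self.patient_predictions = patient_predictions

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def f1(self) -> float:
        return self.report.f1

    @property
    def majority_vote_accuracy(self):
        return self.report.majority_vote_accuracy

    def baselines(self) -> dict[str, float]:
        y = self.model.labels
        return {
            "max_class_guess": max_class_guess(y),
            "random_weighted_guess": random_weighted_guess(y),
        }

    def summary(self) -> str:
        r = self.report
        lines = [
            "Treatment-group classification",
            "=" * 46,
            f"model:            {r.model}",
            f"cross-validation: {r.cv}"
            + (f" (k={self.model.scheme.k})" if r.cv == "kfold" else ""),
            f"unit level:       {r.unit_level}",
            f"features used:    {r.n_features}",
        ]
        for c in (0, 1):
            lines.append(
                f"{GROUP_NAMES[c]}:          {r.correct[c]}/{r.total[c]} correct"
            )
        lines.append(f"accuracy:         {r.accuracy_pct}%")
        lines.append(f"F1 ({GROUP_NAMES[0]} pos): {r.f1:.2f}")
        if r.majority_vote_accuracy is not None:
            lines.append(
                f"majority vote:    {_round_half_up(100 * r.majority_vote_accuracy)}% "
                "(patient level)"
            )
        b = self.baselines()
        lines.append(
            f"baselines:        max-class {b['max_class_guess']:.2f}, "
            f"random-weighted {b['random_weighted_guess']:.2f}"
        )
        return "\n".join(lines)
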