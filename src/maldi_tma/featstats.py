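"""Per-feature discrimination statistics and feature selection.

Two selection procedures are provided:

- threshold screening: keep features whose AUROC (in either direction)
  reaches a threshold *and* whose two-sided Wilcoxon rank-sum p-value is
  at or below a significance gate (the screening rule used to define the
  discriminative peptide panel: AUROC >= 0.7, p <= 0.001);
- greedy forward stepwise selection maximizing inner-cross-validated
  classification accuracy, stopping when the best gain falls below a
  threshold (0.001) or a feature cap is reached.

AUROC is computed with the treated group (LpPRP-1) as the positive class,
so values below 0.5 flag features elevated in untreated tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "auroc",
    "wilcoxon_feature",
    "feature_stats",
    "SelectionConfig",
    "select_by_threshold",
    "ForwardSelectionConfig",
    "forward_select",
]

#: below this pooled size the Wilcoxon p-value is computed by exact
#: enumeration of group-label assignments; above it, by the normal
#: approximation with tie correction
EXACT_WILCOXON_MAX_N = 12


def auroc(values_untreated, values_treated) -> float:
    """Area under the ROC curve with the treated group as positive class.

    Equals the probability that a random treated value exceeds a random
    untreated one, counting ties as one half:
    ``(#pairs treated > untreated + 0.5 * #ties) / (n0 * n1)``.
    Computed from midranks of the pooled sample.
    """
    x0 = np.asarray(values_untreated, dtype=float)
    x1 = np.asarray(values_treated, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([x0, x1]))
    r1 = ranks[x0.size :].sum()
    u1 = r1 - x1.size * (x1.size + 1) / 2.0
    return float(u1 / (x0.size * x1.size))


def _exact_rank_sum_p(x0: np.ndarray, x1: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating label assignments."""
    pooled = np.concatenate([x0, x1])
    n = pooled.size
    ranks = rankdata(pooled)
    n1 = x1.size
    observed = ranks[x0.size :].sum()
    mu = n1 * (n + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        stat = ranks[list(idx)].sum()
        if abs(stat - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_feature(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for one feature.

    Exact enumeration of label assignments for pooled sizes up to
    ``EXACT_WILCOXON_MAX_N`` (correct under ties), normal approximation
    with tie correction above.  Constant pooled data yields p = 1 by
    convention.
    """
    x0 = np.asarray(values_a, dtype=float)
    x1 = np.asarray(values_b, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([x0, x1])
    if np.all(pooled == pooled[0]):
        return 1.0
    if pooled.size <= EXACT_WILCOXON_MAX_N:
        return _exact_rank_sum_p(x0, x1)
    return float(mannwhitneyu(x0, x1, alternative="two-sided", method="asymptotic").pvalue)


def feature_stats(fm, labels, panel=None) -> pd.DataFrame:
    """Per-feature AUROC, Wilcoxon p and direction over a feature matrix.

    Parameters
    ----------
    fm : FeatureMatrix
        Fixed unit level (typically patient mean spectra).
    labels : array-like of 0/1 aligned with ``fm.unit_ids``.
    panel : FeaturePanel, optional
        If given, features whose bin contains a planted m/z inherit its
        annotation text.

    Returns a DataFrame with columns ``mz``, ``auroc``, ``p_value``,
    ``direction``, ``annotation``, one row per feature, in m/z order.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != fm.n_units:
        raise ValueError("labels must align with feature-matrix units")
    x0 = fm.values[y == 0]
    x1 = fm.values[y == 1]
    rows = []
    half_width = np.median(np.diff(fm.mz_bins)) / 2.0 if fm.n_features > 1 else np.inf
    annot_for = {}
    if panel is not None:
        for e in panel.entries:
            j = int(np.argmin(np.abs(fm.mz_bins - e.mz)))
            if abs(fm.mz_bins[j] - e.mz) <= max(half_width, 0.5):
                annot_for[j] = e.annotation
    for j in range(fm.n_features):
        a = auroc(x0[:, j], x1[:, j])
        p = wilcoxon_feature(x0[:, j], x1[:, j])
        rows.append(
            {
                "mz": fm.mz_bins[j],
                "auroc": a,
                "p_value": p,
                "direction": "up_in_treated" if a > 0.5 else "up_in_untreated",
                "annotation": annot_for.get(j),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SelectionConfig:
    """Threshold screening rule."""

    auroc_threshold: float = 0.7
    p_threshold: float = 0.001
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.auroc_threshold < 1.0:
            raise ValueError("auroc_threshold must be in (0.5, 1)")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


def select_by_threshold(stats: pd.DataFrame, cfg: SelectionConfig | None = None) -> list[float]:
    """m/z of features passing the AUROC + p-value screen, in m/z order.

    With ``two_sided`` (default) the AUROC criterion is
    ``max(auroc, 1 - auroc) >= threshold`` so features elevated in either
    group qualify.  An empty selection is a valid result.
    """
    cfg = cfg or SelectionConfig()
    a = stats["auroc"].to_numpy()
    eff = np.maximum(a, 1.0 - a) if cfg.two_sided else a
    keep = (eff >= cfg.auroc_threshold) & (stats["p_value"].to_numpy() <= cfg.p_threshold)
    return sorted(stats.loc[keep, "mz"].tolist())


@dataclass
class ForwardSelectionConfig:
    gain_threshold: float = 0.001
    max_features: int = 9
    inner_cv_folds: int = 5
    seed: int = 0
    #: candidates examined per step: the pool is the features ranked by
    #: |AUROC - 0.5| on the training data (keeps the greedy search tractable)
    candidate_pool: int = 64

    def __post_init__(self) -> None:
        if self.gain_threshold <= 0:
            raise ValueError("gain_threshold must be > 0")
        if self.max_features < 1 or self.inner_cv_folds < 2:
            raise ValueError("max_features >= 1 and inner_cv_folds >= 2 required")


def _lda_accuracy(X: np.ndarray, y: np.ndarray, folds) -> float:
    """Cross-validated accuracy of a small closed-form binary LDA."""
    correct = 0
    for tr, te in folds:
        Xtr, ytr = X[tr], y[tr]
        m0 = Xtr[ytr == 0].mean(axis=0)
        m1 = Xtr[ytr == 1].mean(axis=0)
        Xc = Xtr - np.where(ytr[:, None] == 0, m0, m1)
        n0 = int((ytr == 0).sum())
        n1 = int((ytr == 1).sum())
        cov = Xc.T @ Xc / max(len(tr) - 2, 1)
        cov = cov + 1e-9 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        w = np.linalg.solve(cov, m1 - m0)
        b = -0.5 * w @ (m0 + m1) + math.log(n1 / n0)
        pred = (X[te] @ w + b > 0).astype(int)
        correct += int((pred == y[te]).sum())
    return correct / len(y)


def _svm_accuracy(X: np.ndarray, y: np.ndarray, folds) -> float:
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    correct = 0
    for tr, te in folds:
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def forward_select(
    fm,
    labels,
    model: str = "lda",
    cfg: ForwardSelectionConfig | None = None,
) -> tuple[list[float], list[float]]:
    """Greedy forward stepwise feature selection.

    At each step the feature maximizing inner stratified k-fold accuracy
    is added; the procedure stops when the best achievable gain drops
    below ``gain_threshold`` or ``max_features`` is reached.  Ties in
    accuracy are broken toward lower m/z for determinism.

    Returns ``(selected_mz, accuracy_trace)`` where the trace holds the
    inner-CV accuracy after each accepted step.
    """
    cfg = cfg or ForwardSelectionConfig()
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("forward selection needs both classes present")
    X = fm.values
    mz = fm.mz_bins

    counts = np.bincount(y, minlength=2)
    n_folds = min(cfg.inner_cv_folds, counts.min())
    if n_folds < 2:
        raise ValueError("too few units per class for inner cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed % (2**31))
    folds = list(skf.split(X, y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:  # pragma: no cover - stratified folds
            raise ValueError("degenerate single-class inner fold")

    score = _lda_accuracy if model.lower() == "lda" else _svm_accuracy

    # candidate pool: strongest marginal discriminators first
    margins = np.array([abs(auroc(X[y == 0, j], X[y == 1, j]) - 0.5) for j in range(X.shape[1])])
    pool = np.argsort(-margins, kind="stable")[: cfg.candidate_pool]
    pool = sorted(pool.tolist(), key=lambda j: mz[j])

    selected: list[int] = []
    trace: list[float] = []
    best_acc = -np.inf
    while len(selected) < cfg.max_features:
        best_j, best_new = None, -np.inf
        for j in pool:
            if j in selected:
                continue
            acc = score(X[:, selected + [j]], y, folds)
            if acc > best_new + 1e-12:
                best_new, best_j = acc, j
        # the first feature is always accepted; afterwards the best gain
        # must reach the threshold
        if best_j is None or (selected and best_new - best_acc < cfg.gain_threshold):
            break
        selected.append(best_j)
        trace.append(best_new)
        best_acc = best_new
    return [float(mz[j]) for j in selected], trace
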