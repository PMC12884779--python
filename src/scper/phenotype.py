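"""Phenotype association on estimated cell-type proportions.

Feature ranking by mutual information (nearest-neighbor estimator averaged
over repeats, as the estimator is stochastic), boosted-tree response
classification scored by cross-validated AUROC, and per-cell-type two-group
comparison with the Wilcoxon rank-sum test (BH-adjusted p-values reported
alongside raw ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from statsmodels.stats.multitest import multipletests


@dataclass
class FeatureRanking:
    feature_names: list[str]
    mean_scores: np.ndarray
    per_repeat_scores: np.ndarray  # n_repeats x n_features
    n_repeats: int

    @property
    def order(self) -> np.ndarray:
        """Feature indices sorted by mean MI, descending (stable)."""
        return np.argsort(-self.mean_scores, kind="stable")

    @property
    def ranked_features(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]


def _as_matrix(P, feature_names=None):
    if hasattr(P, "P"):  # ProportionEstimate
        return np.asarray(P.P, dtype=float), list(P.cell_types)
    X = np.atleast_2d(np.asarray(P, dtype=float))
    if feature_names is None:
        feature_names = [f"f{k}" for k in range(X.shape[1])]
    return X, list(feature_names)


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {len(classes)}")
    return (y == classes[1]).astype(int)


def rank_features_mi(
    P, labels, n_repeats: int = 20, seed: int = 0, feature_names=None
) -> FeatureRanking:
    """Average the kNN mutual-information score over ``n_repeats`` runs.

    The estimator (k = 3 neighbors) jitters continuous features internally,
    so repeated runs with distinct derived seeds are averaged for stability.
    """
    X, names = _as_matrix(P, feature_names)
    y = _binary_labels(labels)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("each class needs at least 2 samples")
    rng = np.random.default_rng(seed)
    scores = np.vstack(
        [
            mutual_info_classif(
                X, y, n_neighbors=3, random_state=int(rng.integers(2**31 - 1))
            )
            for _ in range(n_repeats)
        ]
    )
    return FeatureRanking(
        feature_names=names,
        mean_scores=scores.mean(axis=0),
        per_repeat_scores=scores,
        n_repeats=n_repeats,
    )


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    y = _binary_labels(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def select_top_k_and_classify(
    P,
    labels,
    k_grid=None,
    n_splits: int = 5,
    n_cv_repeats: int = 10,
    n_mi_repeats: int = 20,
    seed: int = 0,
    feature_names=None,
) -> tuple[list[str], pd.DataFrame]:
    """Cross-validated AUROC of a boosted classifier on the top-k MI features.

    Returns the chosen features (smallest k maximizing mean AUROC) and a
    table of mean AUROC per k. Folds are stratified so each contains both
    classes.
    """
    import xgboost as xgb

    X, names = _as_matrix(P, feature_names)
    y = _binary_labels(labels)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    ranking = rank_features_mi(X, y, n_repeats=n_mi_repeats, seed=seed, feature_names=names)
    order = ranking.order
    if k_grid is None:
        k_grid = list(range(1, X.shape[1] + 1))

    n_splits_eff = min(n_splits, int(np.bincount(y).min()))
    if n_splits_eff < 2:
        raise ValueError("too few samples in the minority class for cross-validation")
    cv = RepeatedStratifiedKFold(
        n_splits=n_splits_eff, n_repeats=n_cv_repeats, random_state=seed
    )
    rows = []
    for k in k_grid:
        cols = order[:k]
        aucs = []
        for tr, te in cv.split(X, y):
            clf = xgb.XGBClassifier(
                max_depth=3,
                n_estimators=100,
                learning_rate=0.1,
                random_state=seed,
                n_jobs=1,
                verbosity=0,
                eval_metric="logloss",
            )
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            prob = clf.predict_proba(X[np.ix_(te, cols)])[:, 1]
            if y[te].min() == y[te].max():
                continue
            aucs.append(roc_auc_score(y[te], prob))
        rows.append({"k": k, "mean_auroc": float(np.mean(aucs)), "n_folds": len(aucs)})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["mean_auroc"].idxmax(), "k"])  # idxmax -> smallest k on ties
    chosen = [names[i] for i in order[:best_k]]
    return chosen, table


def compare_proportions(P, group_labels, feature_names=None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per cell type between two groups.

    Uses the exact null distribution for small untied groups and the
    tie-corrected normal approximation otherwise. Reports group medians,
    direction of change, raw and Benjamini-Hochberg adjusted p-values.
    """
    X, names = _as_matrix(P, feature_names)
    g = np.asarray(group_labels)
    classes = np.unique(g)
    if len(classes) != 2:
        raise ValueError("exactly two groups are required")
    a_mask, b_mask = g == classes[0], g == classes[1]
    rows = []
    for k, name in enumerate(names):
        a, b = X[a_mask, k], X[b_mask, k]
        if np.all(a[:, None] == b[None, :]):
            p = 1.0  # no rank separation at all
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "feature": name,
                f"median_{classes[0]}": med_a,
                f"median_{classes[1]}": med_b,
                "direction": "up" if med_b > med_a else ("down" if med_b < med_a else "none"),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant_0.05"] = table["p_value"] < 0.05
    return table
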