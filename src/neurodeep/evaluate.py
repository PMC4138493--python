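"""Ground-truth evaluation and the cross-validated classification protocol.

Component matching pairs estimated spatial maps with ground-truth sources by
solving the assignment problem on absolute Pearson correlation (an exact
assignment solver, not a greedy match), resolving each component's sign
ambiguity from the sign of its matched correlation.  Functional network
connectivity (FNC) is the Pearson correlation matrix of component time
courses.  Classification performance is reported as mean +/- sd F-scores
over class-balanced folds for an rbf-kernel SVM, logistic regression and
k-nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class MatchResult:
    """Assignment of estimated components to ground-truth sources."""

    permutation: np.ndarray        # estimated index per true source
    signs: np.ndarray              # +/-1 per matched pair
    sm_corrs: np.ndarray           # |r| of matched spatial maps
    tc_corrs: np.ndarray | None    # |r| of matched time courses
    unmatched: np.ndarray          # estimated components left unassigned

    @property
    def mean_sm_corr(self) -> float:
        return float(self.sm_corrs.mean())

    @property
    def mean_tc_corr(self) -> float:
        return float(self.tc_corrs.mean())


def _cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of A and rows of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return A @ B.T


def match_components(
    est_maps: np.ndarray,
    true_maps: np.ndarray,
    est_tcs: np.ndarray | None = None,
    true_tcs: np.ndarray | None = None,
) -> MatchResult:
    """Optimally assign estimated components to ground-truth sources.

    The assignment maximizes the summed absolute spatial-map correlation
    (model order may exceed the truth; surplus estimates are reported in
    ``unmatched``).  Signs make each matched spatial correlation positive.
    If time courses are given, their absolute correlations are evaluated
    under the spatial assignment, matching the convention that maps drive
    the pairing.
    """
    est_maps = np.atleast_2d(np.asarray(est_maps, float))
    true_maps = np.atleast_2d(np.asarray(true_maps, float))
    if est_maps.shape[1] != true_maps.shape[1]:
        raise ValueError("estimated and true maps must share the voxel dimension")
    n_est, n_true = est_maps.shape[0], true_maps.shape[0]
    if n_est < n_true:
        raise ValueError("fewer estimated components than ground-truth sources")
    R = _cross_corr(est_maps, true_maps)           # (n_est, n_true)
    rows, cols = linear_sum_assignment(-np.abs(R))
    perm = np.empty(n_true, dtype=int)
    perm[cols] = rows
    matched_r = R[perm, np.arange(n_true)]
    signs = np.where(matched_r >= 0, 1, -1)
    unmatched = np.setdiff1d(np.arange(n_est), perm)

    tc_corrs = None
    if est_tcs is not None and true_tcs is not None:
        Rt = _cross_corr(est_tcs.T, true_tcs.T)    # components x sources
        tc_corrs = np.abs(Rt[perm, np.arange(n_true)])
    return MatchResult(permutation=perm, signs=signs,
                       sm_corrs=np.abs(matched_r), tc_corrs=tc_corrs,
                       unmatched=unmatched)


def fnc_matrix(tcs: np.ndarray) -> np.ndarray:
    """Functional network connectivity: Pearson correlations between all
    pairs of component time courses (columns of ``tcs``)."""
    tcs = np.asarray(tcs, float)
    if tcs.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    sd = tcs.std(axis=0)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise ValueError(f"constant time course for component(s) {bad.tolist()}")
    return np.corrcoef(tcs.T)


# ---------------------------------------------------------------------------
# cross-validated classification


@dataclass(frozen=True)
class CVReport:
    """Mean +/- sd F-score per classifier across folds."""

    mean_f: dict
    sd_f: dict
    per_fold: dict
    folds: np.ndarray
    seed: int

    def summary(self) -> str:
        return "\n".join(
            f"{name:>8s} F-score  {self.mean_f[name]:.2f} +/- {self.sd_f[name]:.2f}"
            for name in self.mean_f
        )


def stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Class-balanced fold assignment: per-class seeded shuffle followed by
    round-robin, so per-class fold sizes differ by at most one."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has fewer members ({idx.size}) than folds ({k})")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def default_classifiers(seed: int = 0, tune: bool = False) -> dict:
    """The three off-the-shelf classifiers of the evaluation protocol.

    With ``tune=True`` the SVM's (C, gamma) and kNN's neighbor count are
    selected by an inner 3-fold grid search on the training folds only.
    """
    svm = Pipeline([("scale", StandardScaler()),
                    ("clf", SVC(kernel="rbf", random_state=seed))])
    lr = Pipeline([("scale", StandardScaler()),
                   ("clf", LogisticRegression(max_iter=2000, random_state=seed))])
    knn = KNeighborsClassifier(n_neighbors=5)
    if tune:
        svm = GridSearchCV(svm, {"clf__C": [0.1, 1, 10], "clf__gamma": ["scale", 0.01]}, cv=3)
        knn = GridSearchCV(knn, {"n_neighbors": [3, 5, 9]}, cv=3)
    return {"svm": svm, "logreg": lr, "knn": knn}


def _fscore(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if np.unique(y_true).size <= 2:
        positive = np.max(y_true)
        return float(f1_score(y_true, y_pred, pos_label=positive))
    return float(f1_score(y_true, y_pred, average="macro"))


def crossval_fscores(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    classifiers: dict | None = None,
    seed: int = 0,
) -> CVReport:
    """Class-balanced k-fold cross-validation of the named classifiers.

    Any hyperparameter selection happens inside the training folds (the
    held-out fold is touched only for the final F-score).  Binary problems
    score the patient (largest-label) class; multiclass uses macro
    averaging.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    if classifiers is None:
        classifiers = default_classifiers(seed)
    folds = stratified_folds(y, k, seed)
    per_fold = {name: [] for name in classifiers}
    for fold in range(k):
        test = folds == fold
        if np.unique(y[test]).size < 2 or np.unique(y[~test]).size < 2:
            raise ValueError(f"fold {fold} is degenerate (single class)")
        for name, template in classifiers.items():
            from sklearn.base import clone
            clf = clone(template)
            clf.fit(X[~test], y[~test])
            per_fold[name].append(_fscore(y[test], clf.predict(X[test])))
    per_fold = {name: np.array(v) for name, v in per_fold.items()}
    return CVReport(
        mean_f={name: float(v.mean()) for name, v in per_fold.items()},
        sd_f={name: float(v.std(ddof=1)) for name, v in per_fold.items()},
        per_fold=per_fold, folds=folds, seed=seed,
    )
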