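"""Clinical-utility battery on connectome features.

Case–control discrimination (linear SVC), per-measure interpretation and
treatment-outcome prediction (linear SVR) — all under stratified/ordinary
10-fold cross-validation with label/target-permutation significance — plus
k-means patient subtyping with an elbow criterion and silhouette, and the
printed-table group statistics (pooled-variance two-sample t from summary
statistics, Pearson chi-square without continuity correction).

The feature set entering every model is meant to be the PLSC-significant
edge mask; no further feature selection or hyperparameter tuning is applied
(linear kernel, C = 1), which keeps the permutation null exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from .plsc import fdr_bh

__all__ = [
    "ClassificationReport",
    "RegressionReport",
    "ClusterSolution",
    "classify_patients",
    "regress_measure",
    "cluster_patients",
    "t_from_summary",
    "chi_square_2x2",
    "compare_subgroups",
]


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    perm_p_accuracy: float | None
    perm_p_auc: float | None
    cv_scheme: str
    n_perm: int
    seed: int


@dataclass
class RegressionReport:
    r: float  # Pearson(observed, out-of-fold predictions)
    mse: float  # mean squared error of out-of-fold predictions
    perm_p_r: float | None
    perm_p_mse: float | None
    cv_scheme: str
    n_perm: int
    seed: int


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1..k per patient
    silhouette: float
    inertia_curve: dict  # k -> within-cluster sum of squares (k = 1 included)
    weak_structure: bool  # silhouette < 0.3 at the chosen k
    seed: int


def _oof_predictions(model_factory, X, y, splitter, decision: bool):
    """Pooled out-of-fold predictions (and decision scores for AUC)."""
    pred = np.empty(len(y), dtype=float)
    score = np.empty(len(y), dtype=float) if decision else None
    for train, test in splitter.split(X, y):
        model = model_factory()
        model.fit(X[train], y[train])
        pred[test] = model.predict(X[test])
        if decision:
            score[test] = model.decision_function(X[test])
    return pred, score


def classify_patients(
    features: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationReport:
    """Linear-SVC case–control discrimination under stratified k-fold CV.

    ``labels`` are 1 for patients (cases) and 0 for controls. Accuracy,
    sensitivity (case recall), specificity (control recall) and AUC are
    pooled over held-out folds. Permutation p-values refit the whole CV under
    label shuffles, using the add-one estimator.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    n_splits = min(n_splits, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    def run(yy):
        pred, score = _oof_predictions(lambda: SVC(kernel="linear", C=C), X, yy, skf, True)
        acc = float((pred == yy).mean())
        auc = float(roc_auc_score(yy, score))
        return acc, auc, pred

    acc, auc, pred = run(y)
    sens = float((pred[y == 1] == 1).mean())
    spec = float((pred[y == 0] == 0).mean())
    p_acc = p_auc = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_acc = hits_auc = 0
        for _ in range(n_perm):
            a, u, _ = run(rng.permutation(y))
            hits_acc += a >= acc
            hits_auc += u >= auc
        p_acc = (1 + hits_acc) / (1 + n_perm)
        p_auc = (1 + hits_auc) / (1 + n_perm)
    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        perm_p_accuracy=p_acc,
        perm_p_auc=p_auc,
        cv_scheme=f"stratified {n_splits}-fold, shuffled, seed={seed}",
        n_perm=n_perm,
        seed=seed,
    )


def regress_measure(
    features: np.ndarray,
    target: np.ndarray,
    n_splits: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> RegressionReport:
    """Linear-SVR interpretation/prediction of a continuous measure.

    r is the Pearson correlation between the observed target and pooled
    out-of-fold predictions; MSE is the pooled squared error. Permutation
    p-values shuffle the target (one-sided: larger r, smaller MSE).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if y.std() == 0:
        raise ValueError("target is constant; regression undefined")
    n_splits = min(n_splits, len(y))
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)

    def run(yy):
        pred, _ = _oof_predictions(lambda: SVR(kernel="linear", C=C), X, yy, kf, False)
        r = float(np.corrcoef(yy, pred)[0, 1]) if pred.std() > 0 else 0.0
        mse = float(np.mean((yy - pred) ** 2))
        return r, mse

    r, mse = run(y)
    p_r = p_mse = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_r = hits_mse = 0
        for _ in range(n_perm):
            rr, mm = run(rng.permutation(y))
            hits_r += rr >= r
            hits_mse += mm <= mse
        p_r = (1 + hits_r) / (1 + n_perm)
        p_mse = (1 + hits_mse) / (1 + n_perm)
    return RegressionReport(
        r=r,
        mse=mse,
        perm_p_r=p_r,
        perm_p_mse=p_mse,
        cv_scheme=f"{n_splits}-fold, shuffled, seed={seed}",
        n_perm=n_perm,
        seed=seed,
    )


def cluster_patients(
    features: np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 50,
    pca_components: int | None = None,
) -> ClusterSolution:
    """k-means subtyping with elbow model selection.

    Inertia is computed for k = 1..k_max (k-means++ with ``n_init`` restarts,
    fixed seed); the chosen k maximizes the second difference of the inertia
    curve (the elbow), and the mean silhouette at that k is reported.
    Silhouette < 0.3 flags weak cluster structure. ``pca_components`` applies
    an optional PCA projection first (dimension must be user-specified).
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] <= k_max:
        raise ValueError(f"need more than k_max={k_max} patients, got {X.shape[0]}")
    if np.allclose(X, X[0]):
        raise ValueError("all patients identical; clustering degenerate")
    if pca_components is not None:
        X = PCA(n_components=pca_components, random_state=seed).fit_transform(X)
    inertia: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    inertia[1] = float(((X - X.mean(axis=0)) ** 2).sum())
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels_by_k[k] = km.fit_predict(X)
        inertia[k] = float(km.inertia_)
    # elbow: largest second difference of the inertia curve at interior k
    candidates = range(2, k_max)
    second_diff = {k: inertia[k - 1] - 2 * inertia[k] + inertia[k + 1] for k in candidates}
    k_best = max(candidates, key=lambda k: second_diff[k])
    labels = labels_by_k[k_best] + 1
    sil = float(silhouette_score(X, labels))
    return ClusterSolution(
        k=k_best,
        labels=labels,
        silhouette=sil,
        inertia_curve=inertia,
        weak_structure=sil < 0.3,
        seed=seed,
    )


@dataclass
class TwoSampleTest:
    statistic: float
    df: float
    p: float
    kind: str  # "pooled_t" or "chi_square"


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TwoSampleTest:
    """Pooled-variance (Student) two-sample t from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return TwoSampleTest(statistic=0.0, df=df, p=1.0, kind="pooled_t")
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TwoSampleTest(statistic=float(t), df=df, p=float(p), kind="pooled_t")


def chi_square_2x2(table: np.ndarray) -> TwoSampleTest:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected count <= 0")
    return TwoSampleTest(statistic=float(chi2), df=dof, p=float(p), kind="chi_square")


def compare_subgroups(
    clinical: pd.DataFrame,
    improvements: pd.DataFrame | None,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-measure two-cluster comparison with BH-FDR across measures.

    Continuous columns use the pooled-variance t-test; categorical columns
    (non-numeric dtype) use Pearson chi-square without continuity correction.
    ``improvements`` columns, if given, are appended to the tested family.
    """
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError(f"need exactly 2 subgroups, got {groups.tolist()}")
    if min((lab == g).sum() for g in groups) < 2:
        raise ValueError("each subgroup needs at least 2 patients")
    table = clinical if improvements is None else pd.concat(
        [clinical.reset_index(drop=True), improvements.reset_index(drop=True)], axis=1
    )
    rows = []
    for col in table.columns:
        x = table[col]
        if pd.api.types.is_numeric_dtype(x):
            a = x.to_numpy(dtype=float)[lab == groups[0]]
            b = x.to_numpy(dtype=float)[lab == groups[1]]
            res = t_from_summary(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        else:
            ct = pd.crosstab(lab, x)
            res = chi_square_2x2(ct.to_numpy())
        rows.append((col, res.kind, res.statistic, res.p))
    out = pd.DataFrame(rows, columns=["measure", "test", "statistic", "p"]).set_index("measure")
    out["q_fdr"], out["sig"] = fdr_bh(out["p"].to_numpy(), alpha=alpha)
    return out
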