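"""Post-hoc statistics on best-model parameter sets.

The pipeline that turns pooled best-model parameter values into a
subtype-discrimination report: column standardization, pairwise Pearson
correlations, stepwise linear discriminant variable selection (forward
entry / backward removal on the partial-F of the Wilks' lambda
reduction), hierarchical (Ward) clustering scored by the
Calinski–Harabasz pseudo-F to choose the number of clusters, and a
disjoint (k-means) clustering yielding centroids, centroid distances and
a cluster × subtype confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "standardize",
    "correlation_matrix",
    "stepwise_discriminant",
    "choose_k",
    "disjoint_cluster",
    "ClusterReport",
    "subtype_report",
]


def standardize(X: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Z-score each column (mean 0, sd 1, ddof=1); errors on constant columns."""
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (
            [X.columns[i] for i in bad] if isinstance(X, pd.DataFrame) else list(bad)
        )
        raise ValueError(f"constant column(s): {names}")
    Z = (values - values.mean(axis=0)) / sd
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z


def correlation_matrix(X: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r with two-sided p-values.

    Zero-variance columns yield nan rows/columns (flagged by a warning from
    scipy); the diagonal is exactly 1.
    """
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    n, p = values.shape
    if n < 3:
        raise ValueError("correlation requires at least 3 rows")
    r = np.eye(p)
    pv = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            res = stats.pearsonr(values[:, i], values[:, j])
            r[i, j] = r[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    return r, pv


# ---------------------------------------------------------------------------
# stepwise discriminant analysis
# ---------------------------------------------------------------------------

def _wilks_lambda(Z: np.ndarray, labels: np.ndarray, cols: Sequence[int]) -> float:
    """Wilks' lambda = |W| / |T| for the given column subset."""
    sub = Z[:, list(cols)]
    grand = sub.mean(axis=0)
    T = (sub - grand).T @ (sub - grand)
    W = np.zeros_like(T)
    for g in np.unique(labels):
        grp = sub[labels == g]
        c = grp - grp.mean(axis=0)
        W += c.T @ c
    detT = np.linalg.det(T)
    if detT == 0:
        return 1.0
    return float(np.linalg.det(W) / detT)


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p: int) -> float:
    """Partial F for the variable distinguishing the two nested subsets.

    ``lam_small`` is Wilks' lambda without the variable (p columns),
    ``lam_big`` with it (p+1 columns); g groups, n observations.
    """
    if lam_big <= 0:
        return np.inf
    ratio = lam_small / lam_big - 1.0
    dfe = n - g - p
    if dfe <= 0:
        return 0.0
    return max(ratio, 0.0) * dfe / (g - 1)


def stepwise_discriminant(
    Z: np.ndarray | pd.DataFrame,
    labels: Sequence,
    enter_p: float = 0.15,
    stay_p: float = 0.15,
) -> list:
    """Greedy forward/backward variable selection for linear class separation.

    At each forward step the candidate with the largest partial F enters if
    its p-value is below ``enter_p``; backward steps remove any selected
    variable whose partial F p-value has risen above ``stay_p``.  Ties are
    broken by column order.  Columns that make the within-class scatter
    singular are skipped with a warning.
    """
    if isinstance(Z, pd.DataFrame):
        names = list(Z.columns)
        values = Z.to_numpy(dtype=float)
    else:
        values = np.asarray(Z, dtype=float)
        names = list(range(values.shape[1]))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("stepwise discriminant expects exactly two classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} needs at least 2 rows")
    n, p = values.shape
    g = len(classes)
    selected: list[int] = []
    while True:
        changed = False
        # forward step
        lam_cur = _wilks_lambda(values, labels, selected) if selected else 1.0
        best_j, best_F, best_pv = None, -np.inf, 1.0
        for j in range(p):
            if j in selected:
                continue
            lam_new = _wilks_lambda(values, labels, selected + [j])
            if not np.isfinite(lam_new) or lam_new <= 1e-12:
                continue  # singular within-class scatter
            F = _partial_f(lam_cur, lam_new, n, g, len(selected))
            dfe = n - g - len(selected)
            pv = stats.f.sf(F, g - 1, dfe) if dfe > 0 else 1.0
            if F > best_F:
                best_j, best_F, best_pv = j, F, pv
        if best_j is not None and best_pv < enter_p:
            selected.append(best_j)
            changed = True
        # backward step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            lam_full = _wilks_lambda(values, labels, selected)
            worst_j, worst_F, worst_pv = None, np.inf, 0.0
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = _wilks_lambda(values, labels, rest) if rest else 1.0
                F = _partial_f(lam_rest, lam_full, n, g, len(rest))
                dfe = n - g - len(rest)
                pv = stats.f.sf(F, g - 1, dfe) if dfe > 0 else 1.0
                if F < worst_F:
                    worst_j, worst_F, worst_pv = j, F, pv
            if worst_j is not None and worst_pv > stay_p:
                selected.remove(worst_j)
                removed = True
                changed = True
        if not changed:
            break
    return [names[j] for j in selected]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def choose_k(Z: np.ndarray | pd.DataFrame, kmax: int = 6) -> int:
    """Number of clusters by Ward-linkage hierarchy scored with pseudo-F.

    Cuts the Ward tree at k = 2…kmax and returns the k maximizing the
    Calinski–Harabasz pseudo-F.
    """
    values = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    if len(values) < kmax:
        raise ValueError(f"need at least kmax={kmax} rows")
    link = linkage(values, method="ward")
    best_k, best_score = 2, -np.inf
    for k in range(2, kmax + 1):
        assign = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(assign)) < 2:
            continue
        score = calinski_harabasz_score(values, assign)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


@dataclass
class ClusterReport:
    assignments: np.ndarray
    centroids: np.ndarray
    centroid_distances: np.ndarray    # (k, k) Euclidean
    confusion: pd.DataFrame           # cluster × subtype counts
    inertia: float


def disjoint_cluster(
    Z: np.ndarray | pd.DataFrame,
    k: int,
    labels: Optional[Sequence] = None,
    seed: int = 0,
) -> ClusterReport:
    """Disjoint (k-means) clustering with deterministic k-means++ seeding.

    Returns assignments, centroids, pairwise centroid Euclidean distances
    and — when subtype ``labels`` are given — the cluster × subtype
    confusion matrix.
    """
    values = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    if k > len(values):
        raise ValueError("k exceeds number of rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(values)
    if len(np.unique(assign)) < k:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed + 1)
        assign = km.fit_predict(values)
        if len(np.unique(assign)) < k:
            raise RuntimeError("empty cluster after re-seeding")
    centroids = km.cluster_centers_
    dists = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if labels is not None:
        confusion = pd.crosstab(
            pd.Series(np.asarray(labels), name="subtype"),
            pd.Series(assign, name="cluster"),
        )
    else:
        confusion = pd.DataFrame()
    return ClusterReport(
        assignments=assign,
        centroids=centroids,
        centroid_distances=dists,
        confusion=confusion,
        inertia=float(km.inertia_),
    )


def subtype_report(
    X: pd.DataFrame,
    labels: Sequence,
    kmax: int = 6,
    seed: int = 0,
) -> dict:
    """Full chain: standardize → stepwise selection → choose k → k-means.

    Returns the selected variables, chosen k, cluster report and the
    fraction of rows whose cluster majority-subtype matches their label.
    """
    Z = standardize(X)
    selected = stepwise_discriminant(Z, labels)
    if not selected:
        return {"selected": [], "k": 0, "report": None, "accuracy": 0.0}
    Zsel = Z[selected]
    k = choose_k(Zsel, kmax=min(kmax, len(Zsel) - 1))
    report = disjoint_cluster(Zsel, k, labels=labels, seed=seed)
    conf = report.confusion
    # majority-label accuracy: each cluster votes for its dominant subtype
    correct = sum(conf[c].max() for c in conf.columns)
    accuracy = correct / conf.to_numpy().sum()
    return {"selected": selected, "k": k, "report": report, "accuracy": float(accuracy)}
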