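"""Feature-selection registry: 15 ranking methods.

Three filter scores central to the analysis (t-score, Fisher f-score and the
trace-ratio criterion) are implemented natively.  The remainder of the
registry covers the common filter families: chi-square and kNN-based mutual
information (via scikit-learn), ReliefF, univariate Gini impurity decrease,
a lasso regularization-path ranking, and the discretized information-
theoretic family (MIM, MIFS, mRMR, CIFE, CMIM, JMI, DISR) built on shared
contingency-table MI helpers with greedy forward selection.

Every selector is a function ``(X, y, k) -> ranked indices`` that is
deterministic and invariant to feature column order up to an index
tie-break; name-level tie-breaking happens in the benchmarking layer, which
passes columns in sorted-name order.
"""

from __future__ import annotations

import numpy as np
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import lasso_path
from scipy.spatial.distance import cdist


def _rank_by_score(scores: np.ndarray, k: int) -> np.ndarray:
    """Descending score order with stable index tie-break."""
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=-np.inf)
    order = np.argsort(-scores, kind="stable")
    return order[:k]


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"selectors require exactly two classes, got {classes}")
    g0 = X[y == classes[0]]
    g1 = X[y == classes[1]]
    return g0, g1


def t_score(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Welch-style two-sample t statistic |mu1-mu2| / sqrt(s1^2/n1 + s2^2/n2)."""
    g0, g1 = _class_stats(X, y)
    denom = np.sqrt(g0.var(axis=0, ddof=1) / len(g0) + g1.var(axis=0, ddof=1) / len(g1))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.abs(g0.mean(axis=0) - g1.mean(axis=0)) / denom
    scores[~np.isfinite(scores)] = 0.0
    return _rank_by_score(scores, k)


def _fisher_components(X: np.ndarray, y: np.ndarray):
    g0, g1 = _class_stats(X, y)
    mu = X.mean(axis=0)
    between = len(g0) * (g0.mean(axis=0) - mu) ** 2 + len(g1) * (g1.mean(axis=0) - mu) ** 2
    within = len(g0) * g0.var(axis=0) + len(g1) * g1.var(axis=0)
    return between, within


def f_score(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Fisher score: between-class scatter over within-class scatter."""
    between, within = _fisher_components(X, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = between / within
    scores[~np.isfinite(scores)] = 0.0
    return _rank_by_score(scores, k)


def trace_ratio(X: np.ndarray, y: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Trace-ratio criterion: the k-subset maximizing tr(S_b)/tr(S_w).

    Iteratively re-scores features as ``b_f - lambda * w_f`` where lambda is
    the trace ratio of the currently selected subset; converges in a few
    iterations and is deterministic.
    """
    between, within = _fisher_components(X, y)
    within = np.maximum(within, 1e-12)
    lam = between.sum() / within.sum()
    selected = _rank_by_score(between - lam * within, k)
    for _ in range(max_iter):
        lam_new = between[selected].sum() / within[selected].sum()
        new_sel = _rank_by_score(between - lam_new * within, k)
        if np.array_equal(new_sel, selected):
            break
        selected, lam = new_sel, lam_new
    return selected


def chi_square(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Chi-square statistic on min-max scaled (non-negative) features."""
    lo = X.min(axis=0)
    span = np.maximum(X.max(axis=0) - lo, 1e-12)
    scores, _ = _sk_chi2((X - lo) / span, y)
    return _rank_by_score(scores, k)


def mutual_info_max(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """kNN-estimated mutual information with the class label."""
    scores = mutual_info_classif(X, y, random_state=0)
    return _rank_by_score(scores, k)


def relieff(X: np.ndarray, y: np.ndarray, k: int, n_neighbors: int = 5) -> np.ndarray:
    """ReliefF weights from nearest in-class hits and out-of-class misses."""
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-12)
    Z = (X - mu) / sd
    span = np.maximum(Z.max(axis=0) - Z.min(axis=0), 1e-12)
    n = len(Z)
    m = min(n_neighbors, n - 1)
    d = cdist(Z, Z)
    np.fill_diagonal(d, np.inf)
    w = np.zeros(X.shape[1])
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        diff = np.flatnonzero(y != y[i])
        same = same[same != i]
        hits = same[np.argsort(d[i, same], kind="stable")[:m]]
        misses = diff[np.argsort(d[i, diff], kind="stable")[:m]]
        if len(hits):
            w -= np.abs(Z[i] - Z[hits]).mean(axis=0) / span
        if len(misses):
            w += np.abs(Z[i] - Z[misses]).mean(axis=0) / span
    return _rank_by_score(w, k)


def gini_index(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Best single-threshold Gini impurity decrease per feature."""
    n = len(y)
    p1 = y.mean()
    parent = 1.0 - p1**2 - (1 - p1) ** 2
    scores = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        ys = y[order]
        cum1 = np.cumsum(ys)[:-1]
        nl = np.arange(1, n)
        nr = n - nl
        pl1 = cum1 / nl
        pr1 = (cum1[-1] + ys[-1] - cum1) / nr
        gini_l = 1 - pl1**2 - (1 - pl1) ** 2
        gini_r = 1 - pr1**2 - (1 - pr1) ** 2
        child = (nl * gini_l + nr * gini_r) / n
        scores[f] = parent - child.min()
    return _rank_by_score(scores, k)


def lasso_path_rank(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Rank by order of entry along the lasso regularization path."""
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-12)
    Z = (X - mu) / sd
    yy = np.where(y == np.unique(y)[1], 1.0, -1.0)
    alphas, coefs, _ = lasso_path(Z, yy, n_alphas=100)
    nonzero = np.abs(coefs) > 1e-12
    # entry alpha: the largest alpha (first path index) at which a feature is active
    entry = np.full(X.shape[1], np.inf)
    final = np.abs(coefs[:, -1])
    for f in range(X.shape[1]):
        hits = np.flatnonzero(nonzero[f])
        if hits.size:
            entry[f] = hits[0]
    scores = -entry + 1e-9 * final  # earlier entry first, |coef| as tie-break
    return _rank_by_score(scores, k)


# -- discretized information-theoretic family -------------------------------

def _quantile_discretize(X: np.ndarray, n_bins: int = 4) -> np.ndarray:
    out = np.zeros(X.shape, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for f in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, f], qs))
        out[:, f] = np.searchsorted(edges, X[:, f], side="right")
    return out


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _joint_counts(*cols: np.ndarray) -> np.ndarray:
    dims = [int(c.max()) + 1 for c in cols]
    idx = np.ravel_multi_index(tuple(cols), dims)
    return np.bincount(idx, minlength=int(np.prod(dims))).astype(float)


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    return (
        _entropy_from_counts(_joint_counts(a))
        + _entropy_from_counts(_joint_counts(b))
        - _entropy_from_counts(_joint_counts(a, b))
    )


def _cmi(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """I(a;b|c) via the chain of joint entropies."""
    return (
        _entropy_from_counts(_joint_counts(a, c))
        + _entropy_from_counts(_joint_counts(b, c))
        - _entropy_from_counts(_joint_counts(a, b, c))
        - _entropy_from_counts(_joint_counts(c))
    )


def _greedy_mi_selector(redundancy):
    """Build a greedy forward selector with a given redundancy functional.

    ``redundancy(rel, f, selected, Xd, y)`` returns the criterion value of
    candidate ``f`` given already-selected features.
    """

    def select(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
        Xd = _quantile_discretize(X)
        yd = y.astype(np.int64)
        n_feat = X.shape[1]
        rel = np.array([_mi(Xd[:, f], yd) for f in range(n_feat)])
        selected: list[int] = [int(np.argmax(rel))]
        while len(selected) < min(k, n_feat):
            best_f, best_val = -1, -np.inf
            for f in range(n_feat):
                if f in selected:
                    continue
                val = redundancy(rel, f, selected, Xd, yd)
                if val > best_val + 1e-15:
                    best_f, best_val = f, val
            selected.append(best_f)
        return np.asarray(selected[:k])

    return select


def mim(X, y, k):
    """Mutual-information maximization on quantile-discretized features."""
    Xd = _quantile_discretize(X)
    yd = y.astype(np.int64)
    scores = np.array([_mi(Xd[:, f], yd) for f in range(X.shape[1])])
    return _rank_by_score(scores, k)


def _mifs_red(rel, f, sel, Xd, yd, beta=0.5):
    return rel[f] - beta * sum(_mi(Xd[:, f], Xd[:, s]) for s in sel)


def _mrmr_red(rel, f, sel, Xd, yd):
    return rel[f] - np.mean([_mi(Xd[:, f], Xd[:, s]) for s in sel])


def _cife_red(rel, f, sel, Xd, yd):
    return rel[f] - sum(
        _mi(Xd[:, f], Xd[:, s]) - _cmi(Xd[:, f], Xd[:, s], yd) for s in sel
    )


def _cmim_red(rel, f, sel, Xd, yd):
    return rel[f] - max(
        _mi(Xd[:, f], Xd[:, s]) - _cmi(Xd[:, f], Xd[:, s], yd) for s in sel
    )


def _jmi_red(rel, f, sel, Xd, yd):
    return rel[f] - np.mean(
        [_mi(Xd[:, f], Xd[:, s]) - _cmi(Xd[:, f], Xd[:, s], yd) for s in sel]
    )


def _disr_red(rel, f, sel, Xd, yd):
    total = 0.0
    for s in sel:
        pair = Xd[:, f] * (Xd[:, s].max() + 1) + Xd[:, s]
        joint_mi = _mi(pair, yd)
        h = _entropy_from_counts(_joint_counts(pair, yd))
        total += joint_mi / h if h > 0 else 0.0
    return total


mifs = _greedy_mi_selector(_mifs_red)
mrmr = _greedy_mi_selector(_mrmr_red)
cife = _greedy_mi_selector(_cife_red)
cmim = _greedy_mi_selector(_cmim_red)
jmi = _greedy_mi_selector(_jmi_red)
disr = _greedy_mi_selector(_disr_red)


SELECTOR_REGISTRY: dict[str, callable] = {
    "t_score": t_score,
    "f_score": f_score,
    "trace_ratio": trace_ratio,
    "chi_square": chi_square,
    "mutual_info_max": mutual_info_max,
    "mrmr": mrmr,
    "relieff": relieff,
    "gini": gini_index,
    "cife": cife,
    "cmim": cmim,
    "jmi": jmi,
    "disr": disr,
    "mim": mim,
    "mifs": mifs,
    "lasso_path": lasso_path_rank,
}

assert len(SELECTOR_REGISTRY) == 15
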