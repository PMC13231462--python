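"""Feature selection: five rankers/searchers over the feature table.

All methods are deterministic given (X, y, method, seed) and return an
ordered list of column indices of size <= k.

* ``stepwise`` — bidirectional add/drop against a linear least-squares fit
  of the one-hot class indicator, with partial-F entry (p < 0.05) and
  removal (p > 0.10) thresholds.
* ``mrmr`` — greedy maximum-relevance-minimum-redundancy: relevance is the
  mutual information of a feature with the class; redundancy is the mean
  mutual information (quartile-binned) with already-selected features.
* ``relieff`` — ReliefF neighbour-margin weighting with 10 nearest hits
  and misses per class, evaluated at every sample.
* ``chi2`` — chi-square statistic of the quartile-binned feature against
  the class.
* ``mutual_info`` — k-NN mutual-information estimator ranking.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import mutual_info_score

from .errors import InvalidArgumentError

__all__ = ["SELECTORS", "select_features"]

SELECTORS = ("stepwise", "mrmr", "relieff", "chi2", "mutual_info")


def _quartile_bins(x: np.ndarray) -> np.ndarray:
    edges = np.quantile(x, [0.25, 0.5, 0.75])
    return np.searchsorted(edges, x, side="right")


def _one_hot(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    return (y[:, None] == classes[None, :]).astype(float)


def _rss(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares of least-squares fit X -> Y (with intercept)."""
    A = np.column_stack([np.ones(len(X)), X]) if X.size else np.ones((len(Y), 1))
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coef
    return float((resid**2).sum())


def _partial_f_p(rss_small: float, rss_big: float, df_extra: int, df_resid: int) -> float:
    if rss_big <= 0 or df_resid <= 0:
        return 0.0
    f = ((rss_small - rss_big) / df_extra) / (rss_big / df_resid)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, df_extra, df_resid))


def _stepwise(X: np.ndarray, y: np.ndarray, k: int,
              p_enter: float = 0.05, p_remove: float = 0.10) -> list[int]:
    Y = _one_hot(y)
    n, p = X.shape
    n_out = Y.shape[1]
    selected: list[int] = []
    changed = True
    while changed and len(selected) < k:
        changed = False
        # forward step: best candidate by partial-F p-value
        rss_cur = _rss(X[:, selected], Y)
        best_j, best_p = None, p_enter
        for j in range(p):
            if j in selected:
                continue
            rss_new = _rss(X[:, selected + [j]], Y)
            df_resid = n_out * n - (len(selected) + 2) * n_out
            pv = _partial_f_p(rss_cur, rss_new, n_out, max(df_resid, 1))
            if pv < best_p:
                best_p, best_j = pv, j
        if best_j is not None:
            selected.append(best_j)
            changed = True
        # backward step: drop any feature whose removal p exceeds threshold
        if len(selected) > 1:
            rss_full = _rss(X[:, selected], Y)
            worst_j, worst_p = None, p_remove
            for j in selected:
                rest = [s for s in selected if s != j]
                rss_wo = _rss(X[:, rest], Y)
                df_resid = n_out * n - (len(selected) + 1) * n_out
                pv = _partial_f_p(rss_wo, rss_full, n_out, max(df_resid, 1))
                if pv > worst_p:
                    worst_p, worst_j = pv, j
            if worst_j is not None:
                selected.remove(worst_j)
                changed = True
    return selected[:k]


def _mrmr(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> list[int]:
    p = X.shape[1]
    relevance = mutual_info_classif(X, y, random_state=seed)
    binned = [_quartile_bins(X[:, j]) for j in range(p)]
    selected = [int(np.argmax(relevance))]
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            red = np.mean([mutual_info_score(binned[j], binned[s]) for s in selected])
            score = relevance[j] - red
            if score > best_score:
                best_score, best_j = score, j
        selected.append(best_j)
    return selected


def _relieff(X: np.ndarray, y: np.ndarray, k: int, n_neighbors: int = 10) -> list[int]:
    n, p = X.shape
    rng_range = X.max(axis=0) - X.min(axis=0)
    rng_range[rng_range == 0] = 1.0
    Xn = (X - X.min(axis=0)) / rng_range
    classes, y_idx = np.unique(y, return_inverse=True)
    priors = np.bincount(y_idx) / n
    d2 = ((Xn[:, None, :] - Xn[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = y_idx == y_idx[i]
        hit_pool = np.flatnonzero(same)
        hit_pool = hit_pool[hit_pool != i]
        hits = hit_pool[np.argsort(d2[i, hit_pool], kind="stable")[:n_neighbors]]
        if len(hits):
            w -= np.abs(Xn[i] - Xn[hits]).mean(axis=0) / n
        for c in range(len(classes)):
            if c == y_idx[i]:
                continue
            pool = np.flatnonzero(y_idx == c)
            miss = pool[np.argsort(d2[i, pool], kind="stable")[:n_neighbors]]
            if len(miss):
                wgt = priors[c] / (1.0 - priors[y_idx[i]])
                w += wgt * np.abs(Xn[i] - Xn[miss]).mean(axis=0) / n
    return list(np.argsort(-w, kind="stable")[:k])


def _chi2_rank(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    stats_ = []
    for j in range(X.shape[1]):
        b = _quartile_bins(X[:, j])
        ct = np.zeros((b.max() + 1, len(np.unique(y))))
        classes = {c: i for i, c in enumerate(np.unique(y))}
        for bi, yi in zip(b, y):
            ct[bi, classes[yi]] += 1
        ct = ct[ct.sum(axis=1) > 0][:, ct.sum(axis=0) > 0]
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            stats_.append(0.0)
            continue
        chi2, *_ = stats.chi2_contingency(ct)
        stats_.append(float(chi2))
    return list(np.argsort(-np.asarray(stats_), kind="stable")[:k])


def _mi_rank(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> list[int]:
    mi = mutual_info_classif(X, y, random_state=seed)
    return list(np.argsort(-mi, kind="stable")[:k])


def select_features(method: str, X: np.ndarray, y: np.ndarray, k: int,
                    seed: int = 0) -> list[int]:
    """Ordered indices of the selected feature subset (size <= k)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k > X.shape[1]:
        raise InvalidArgumentError("k exceeds the number of feature columns")
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("y must contain at least 2 classes")
    if method == "stepwise":
        sel = _stepwise(X, y, k)
        # an empty stepwise result would leave the classifier featureless;
        # fall back to the univariate chi2 ranking in that degenerate case
        if not sel:
            sel = _chi2_rank(X, y, k)
        return sel[:k]
    if method == "mrmr":
        return _mrmr(X, y, k, seed)
    if method == "relieff":
        return _relieff(X, y, k)
    if method == "chi2":
        return _chi2_rank(X, y, k)
    if method == "mutual_info":
        return _mi_rank(X, y, k, seed)
    raise InvalidArgumentError(f"unknown selector {method!r}")
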