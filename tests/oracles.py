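"""Independent brute-force reference implementations used only by tests.

These deliberately use plain loops and explicit sorting — no shared code
with the package — so that agreement with the package is a meaningful
check rather than a tautology.
"""

import math

import numpy as np


def brute_nan_euclidean(x, y):
    shared = [
        j for j in range(len(x)) if not math.isnan(x[j]) and not math.isnan(y[j])
    ]
    if not shared:
        return None
    total = len(x)
    s = sum((x[j] - y[j]) ** 2 for j in shared)
    return math.sqrt(total / len(shared) * s)


def brute_knn_impute_table(X: np.ndarray, k: int) -> np.ndarray:
    """Distance-weighted kNN imputation of a samples x features table.

    All pairwise distances, explicit sort with index tie-break, explicit
    weighted mean, zero-distance donors averaged uniformly.
    """
    n = X.shape[0]
    out = X.copy()
    dist = [[None] * n for _ in range(n)]
    for i in range(n):
        for h in range(n):
            if i != h:
                dist[i][h] = brute_nan_euclidean(list(X[i]), list(X[h]))
    for i in range(n):
        for j in range(X.shape[1]):
            if not math.isnan(X[i, j]):
                continue
            donors = [
                h
                for h in range(n)
                if h != i and not math.isnan(X[h, j]) and dist[i][h] is not None
            ]
            donors.sort(key=lambda h: (dist[i][h], h))
            sel = donors[:k]
            if not sel:
                continue
            dists = [dist[i][h] for h in sel]
            if min(dists) == 0.0:
                zeros = [h for h in sel if dist[i][h] == 0.0]
                out[i, j] = sum(X[h, j] for h in zeros) / len(zeros)
            else:
                wsum = sum(1.0 / d for d in dists)
                out[i, j] = sum(X[h, j] / dist[i][h] for h in sel) / wsum
    return out


def brute_knn_impute_quants(vals: np.ndarray, k: int) -> np.ndarray:
    """Reference for plug-in kNN on quant matrices (peptides x runs):
    distances between runs on log2 values, unweighted raw-scale mean."""
    n_pep, n_runs = vals.shape
    logs = np.where(np.isnan(vals), np.nan, np.log2(np.maximum(vals, 1e-12)))
    out = vals.copy()
    for c in range(n_runs):
        dists = {}
        for h in range(n_runs):
            if h != c:
                d = brute_nan_euclidean(list(logs[:, c]), list(logs[:, h]))
                if d is not None:
                    dists[h] = d
        for r in range(n_pep):
            if not math.isnan(vals[r, c]):
                continue
            donors = [h for h in dists if not math.isnan(vals[r, h])]
            donors.sort(key=lambda h: (dists[h], h))
            sel = donors[:k]
            if sel:
                out[r, c] = sum(vals[r, h] for h in sel) / len(sel)
    return out
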