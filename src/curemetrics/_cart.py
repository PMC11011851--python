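"""Deterministic depth-limited CART classifier (Gini impurity).

A minimal axis-aligned decision tree tuned for the leave-one-out
pipelines in :mod:`curemetrics.chemometrics`, where hundreds of
thousands of tiny (≈130 × 2) fits are needed: split search and
prediction are numba-compiled, and tie-breaking is fully deterministic
(first feature, lowest threshold, smallest class index at leaves).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=False)
def _build_tree(X, y, n_classes, max_depth):
    n, d = X.shape
    max_nodes = 2 * n + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    leaf_pred = np.zeros(max_nodes, np.int64)

    idx = np.arange(n)
    stack = np.zeros((max_nodes, 4), np.int64)  # node, start, end, depth
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    n_nodes = 1
    vals = np.empty(n, np.float64)
    tmp = np.empty(n, np.int64)

    while top > 0:
        top -= 1
        node = stack[top, 0]
        s = stack[top, 1]
        e = stack[top, 2]
        depth = stack[top, 3]
        m = e - s

        counts = np.zeros(n_classes, np.int64)
        for i in range(s, e):
            counts[y[idx[i]]] += 1
        best_c = 0
        for c in range(1, n_classes):
            if counts[c] > counts[best_c]:
                best_c = c
        leaf_pred[node] = best_c

        if counts[best_c] == m or m < 2 or (max_depth >= 0 and depth >= max_depth):
            continue

        best_score = -1.0
        best_f = -1
        best_t = 0.0
        best_nl = 0
        for f in range(d):
            for i in range(m):
                vals[i] = X[idx[s + i], f]
            order = np.argsort(vals[:m], kind="mergesort")
            lc = np.zeros(n_classes, np.int64)
            rc = counts.copy()
            for i in range(m - 1):
                c = y[idx[s + order[i]]]
                lc[c] += 1
                rc[c] -= 1
                if vals[order[i]] == vals[order[i + 1]]:
                    continue
                nl = i + 1
                nr = m - nl
                score = 0.0
                for cc in range(n_classes):
                    score += lc[cc] * lc[cc] / nl + rc[cc] * rc[cc] / nr
                if score > best_score + 1e-12:
                    best_score = score
                    best_f = f
                    best_t = 0.5 * (vals[order[i]] + vals[order[i + 1]])
                    best_nl = nl
        if best_f < 0:
            continue  # all feature values identical in this node

        # partition idx[s:e] on X[:, best_f] <= best_t, order-preserving
        p = 0
        for i in range(s, e):
            if X[idx[i], best_f] <= best_t:
                tmp[p] = idx[i]
                p += 1
        for i in range(s, e):
            if X[idx[i], best_f] > best_t:
                tmp[p] = idx[i]
                p += 1
        for i in range(m):
            idx[s + i] = tmp[i]

        node_l = n_nodes
        node_r = n_nodes + 1
        n_nodes += 2
        feat[node] = best_f
        thr[node] = best_t
        left[node] = node_l
        right[node] = node_r
        stack[top, 0] = node_l
        stack[top, 1] = s
        stack[top, 2] = s + best_nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = node_r
        stack[top, 1] = s + best_nl
        stack[top, 2] = e
        stack[top, 3] = depth + 1
        top += 1

    return feat[:n_nodes], thr[:n_nodes], left[:n_nodes], right[:n_nodes], leaf_pred[:n_nodes]


@njit(cache=False)
def _predict_tree(X, feat, thr, left, right, leaf_pred):
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while left[node] != -1:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = leaf_pred[node]
    return out


class DecisionTreeCART:
    """sklearn-like interface over the jitted tree builder."""

    def __init__(self, max_depth: int | None = None):
        self.max_depth = max_depth
        self._tree = None
        self.classes_ = None

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        depth = -1 if self.max_depth is None else int(self.max_depth)
        self._tree = _build_tree(X, y_enc.astype(np.int64), len(self.classes_), depth)
        return self

    def predict(self, X):
        if self._tree is None:
            raise RuntimeError("fit before predict")
        X = np.ascontiguousarray(X, dtype=np.float64)
        enc = _predict_tree(X, *self._tree)
        return self.classes_[enc]


def warmup() -> None:
    """Trigger JIT compilation on a toy problem (done once per process)."""
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([0, 1, 0, 1])
    DecisionTreeCART(max_depth=2).fit(X, y).predict(X)
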