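"""Exact path-dependent Shapley attribution for scikit-learn decision trees.

Implements the polynomial-time tree Shapley-value algorithm: a single
depth-first pass per (record, tree) maintains the set of unique features on
the current root-to-node path together with the proportion of feature
subsets of each size that flow down it ("zero" fraction = proportion of
paths through the node when the split feature is absent from the subset,
"one" fraction = when it is present).  At a leaf, unwinding each path
element yields that feature's weighted marginal contribution.

The attribution satisfies local accuracy w.r.t. the *path-dependent*
expectation: per tree, ``sum(phi) + expected_value == leaf value at x``.
For a classifier tree the node value used is the class-1 probability, so
averaging over an ensemble reproduces ``predict_proba[:, 1]``.

Functions here operate on the flat array representation of
``sklearn.tree._tree.Tree`` and are jitted with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _unwound_sum(pzero, pone, pw, s, d, i):
    """Sum of path weights after (virtually) removing path element ``i``.

    ``d`` is the current element count of the path stored at offset ``s``.
    """
    length = d - 1
    z = pzero[s + i]
    o = pone[s + i]
    total = 0.0
    if o != 0.0:
        nxt = pw[s + length]
        for j in range(length - 1, -1, -1):
            u = nxt * (length + 1) / ((j + 1) * o)
            total += u
            nxt = pw[s + j] - u * z * (length - j) / (length + 1)
    else:
        for j in range(length - 1, -1, -1):
            total += pw[s + j] * (length + 1) / (z * (length - j))
    return total


@njit(cache=False)
def _unwind(pfeat, pzero, pone, pw, s, d, i):
    """Remove path element ``i`` in place, inverting the extension step."""
    length = d - 1
    z = pzero[s + i]
    o = pone[s + i]
    if o != 0.0:
        nxt = pw[s + length]
        for j in range(length - 1, -1, -1):
            u = nxt * (length + 1) / ((j + 1) * o)
            nxt = pw[s + j] - u * z * (length - j) / (length + 1)
            pw[s + j] = u
    else:
        for j in range(length - 1, -1, -1):
            pw[s + j] = pw[s + j] * (length + 1) / (z * (length - j))
    for j in range(i, length):
        pfeat[s + j] = pfeat[s + j + 1]
        pzero[s + j] = pzero[s + j + 1]
        pone[s + j] = pone[s + j + 1]


@njit(cache=False)
def _recurse(cl, cr, nfeat, thr, cover, val, x, phi, pfeat, pzero, pone, pw,
             node, s_parent, depth, pz, po, pi):
    s = s_parent + depth
    for i in range(depth):
        pfeat[s + i] = pfeat[s_parent + i]
        pzero[s + i] = pzero[s_parent + i]
        pone[s + i] = pone[s_parent + i]
        pw[s + i] = pw[s_parent + i]
    # extend the path with the incoming (zero, one, feature) triple
    pfeat[s + depth] = pi
    pzero[s + depth] = pz
    pone[s + depth] = po
    pw[s + depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[s + i + 1] += po * pw[s + i] * (i + 1) / (depth + 1)
        pw[s + i] = pz * pw[s + i] * (depth - i) / (depth + 1)
    d = depth + 1
    if cl[node] < 0:  # leaf
        for i in range(1, d):
            w_sum = _unwound_sum(pzero, pone, pw, s, d, i)
            phi[pfeat[s + i]] += w_sum * (pone[s + i] - pzero[s + i]) * val[node]
    else:
        f = nfeat[node]
        if x[f] <= thr[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        hot_z = cover[hot] / cover[node]
        cold_z = cover[cold] / cover[node]
        iz = 1.0
        io = 1.0
        for i in range(1, d):
            if pfeat[s + i] == f:
                iz = pzero[s + i]
                io = pone[s + i]
                _unwind(pfeat, pzero, pone, pw, s, d, i)
                d -= 1
                break
        _recurse(cl, cr, nfeat, thr, cover, val, x, phi, pfeat, pzero, pone,
                 pw, hot, s, d, hot_z * iz, io, f)
        _recurse(cl, cr, nfeat, thr, cover, val, x, phi, pfeat, pzero, pone,
                 pw, cold, s, d, cold_z * iz, 0.0, f)


def _tree_arrays(tree, class_index: int = 1):
    """Flat arrays plus per-node output values for one fitted sklearn tree."""
    t = tree.tree_
    cl = t.children_left.astype(np.int64)
    cr = t.children_right.astype(np.int64)
    nfeat = t.feature.astype(np.int64)
    thr = t.threshold.astype(np.float64)
    cover = t.weighted_n_node_samples.astype(np.float64)
    raw = t.value
    if raw.ndim == 3 and raw.shape[2] > 1:  # classifier: normalise to class prob
        counts = raw[:, 0, :].astype(np.float64)
        val = counts[:, class_index] / counts.sum(axis=1)
    else:
        val = raw.reshape(len(cl)).astype(np.float64)
    return cl, cr, nfeat, thr, cover, val


def tree_expected_value(tree, class_index: int = 1) -> float:
    """Cover-weighted mean leaf value: the path-dependent E[f]."""
    cl, cr, _, _, cover, val = _tree_arrays(tree, class_index)
    leaves = cl < 0
    return float((val[leaves] * cover[leaves]).sum() / cover[leaves].sum())


def tree_shap_values(tree, X: np.ndarray, class_index: int = 1) -> np.ndarray:
    """Exact Shapley attributions for one tree over the rows of ``X``."""
    cl, cr, nfeat, thr, cover, val = _tree_arrays(tree, class_index)
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    maxd = int(tree.tree_.max_depth) + 2
    buf = (maxd + 2) * (maxd + 3) // 2 + 4
    phi = np.zeros((n, p), dtype=np.float64)
    pfeat = np.empty(buf, dtype=np.int64)
    pzero = np.empty(buf, dtype=np.float64)
    pone = np.empty(buf, dtype=np.float64)
    pw = np.empty(buf, dtype=np.float64)
    for r in range(n):
        _recurse(cl, cr, nfeat, thr, cover, val, X[r], phi[r], pfeat, pzero,
                 pone, pw, 0, 0, 0, 1.0, 1.0, -1)
    return phi


def forest_shap_values(model, X: np.ndarray, class_index: int = 1):
    """Shapley attributions for a fitted sklearn tree ensemble.

    Returns ``(phi, expected_value)`` where ``phi`` is (n, p) and
    ``phi.sum(axis=1) + expected_value`` reproduces the ensemble's class-1
    probability (local accuracy), since the ensemble averages per-tree
    class probabilities.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature mismatch: model expects {model.n_features_in_} columns, "
            f"got {X.shape[1] if X.ndim == 2 else 'non-2d input'}"
        )
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    base = 0.0
    for est in model.estimators_:
        phi += tree_shap_values(est, X, class_index)
        base += tree_expected_value(est, class_index)
    k = len(model.estimators_)
    return phi / k, base / k
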