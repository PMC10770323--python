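"""Exact per-sample Shapley attributions for tree ensembles.

Implements the polynomial-time path-dependent tree-Shapley algorithm: for a
single decision tree, feature attributions are computed by propagating
subset-weight polynomials down each root-to-leaf path, where the "absent
feature" distribution follows the tree's own training-sample split
fractions.  For a random forest the attributions (and the base value) are
the average over trees, so per-sample additivity holds exactly:

    sum_j phi_ij + base = predict_proba(x_i)[positive class].

The per-node recursion is expressed iteratively (explicit stack) and
JIT-compiled with numba; tests validate it against a brute-force Shapley
oracle that enumerates feature subsets on small trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_shap_values", "tree_arrays"]


class UnsupportedModelError(TypeError):
    pass


@njit(cache=False)
def _shap_one(cl, cr, feat, thr, val, w, x, phi, max_depth):
    stride = max_depth + 2
    n_levels = max_depth + 2
    # per-level path buffers: feature id, zero fraction, one fraction, weight
    pd_ = np.empty((n_levels, stride), np.int64)
    pz = np.empty((n_levels, stride), np.float64)
    po = np.empty((n_levels, stride), np.float64)
    pw = np.empty((n_levels, stride), np.float64)

    cap = cl.shape[0] + 2
    s_node = np.empty(cap, np.int64)
    s_level = np.empty(cap, np.int64)
    s_plen = np.empty(cap, np.int64)   # parent path length to copy
    s_pz = np.empty(cap, np.float64)
    s_po = np.empty(cap, np.float64)
    s_pi = np.empty(cap, np.int64)
    s_parent = np.empty(cap, np.int64)  # parent level (copy source), -1 = none

    top = 0
    s_node[top] = 0
    s_level[top] = 0
    s_plen[top] = 0
    s_pz[top] = 1.0
    s_po[top] = 1.0
    s_pi[top] = -1
    s_parent[top] = -1
    top = 1

    while top > 0:
        top -= 1
        node = s_node[top]
        level = s_level[top]
        plen = s_plen[top]
        ppz = s_pz[top]
        ppo = s_po[top]
        ppi = s_pi[top]
        src = s_parent[top]

        # copy parent path into this level's buffer
        if src >= 0:
            for i in range(plen):
                pd_[level, i] = pd_[src, i]
                pz[level, i] = pz[src, i]
                po[level, i] = po[src, i]
                pw[level, i] = pw[src, i]

        # EXTEND with (ppz, ppo, ppi)
        l = plen
        pd_[level, l] = ppi
        pz[level, l] = ppz
        po[level, l] = ppo
        pw[level, l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            pw[level, i + 1] += ppo * pw[level, i] * (i + 1) / (l + 1)
            pw[level, i] = ppz * pw[level, i] * (l - i) / (l + 1)
        plen = l + 1

        if cl[node] < 0:  # leaf
            ud = plen - 1
            leaf = val[node]
            for i in range(1, plen):
                one = po[level, i]
                zero = pz[level, i]
                next_one = pw[level, ud]
                tot = 0.0
                if one != 0.0:
                    for j in range(ud - 1, -1, -1):
                        tmp = next_one * (ud + 1) / ((j + 1) * one)
                        tot += tmp
                        next_one = pw[level, j] - tmp * zero * (ud - j) / (ud + 1)
                else:
                    for j in range(ud - 1, -1, -1):
                        tot += pw[level, j] * (ud + 1) / (zero * (ud - j))
                phi[pd_[level, i]] += tot * (one - zero) * leaf
            continue

        f = feat[node]
        if x[f] <= thr[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        hz = w[hot] / w[node]
        cz = w[cold] / w[node]
        iz = 1.0
        io = 1.0
        # has this feature already been split on along the path?
        kfound = -1
        for i in range(1, plen):
            if pd_[level, i] == f:
                kfound = i
                break
        if kfound >= 0:
            iz = pz[level, kfound]
            io = po[level, kfound]
            # UNWIND element kfound out of the path
            ud = plen - 1
            one = io
            zero = iz
            next_one = pw[level, ud]
            for j in range(ud - 1, -1, -1):
                if one != 0.0:
                    tmp = pw[level, j]
                    pw[level, j] = next_one * (ud + 1) / ((j + 1) * one)
                    next_one = tmp - pw[level, j] * zero * (ud - j) / (ud + 1)
                else:
                    pw[level, j] = pw[level, j] * (ud + 1) / (zero * (ud - j))
            # weights are positional and were recomputed above; only the
            # element fields shift left
            for j in range(kfound, ud):
                pd_[level, j] = pd_[level, j + 1]
                pz[level, j] = pz[level, j + 1]
                po[level, j] = po[level, j + 1]
            plen = ud

        # push cold then hot (hot processed first; order does not matter)
        s_node[top] = cold
        s_level[top] = level + 1
        s_plen[top] = plen
        s_pz[top] = cz * iz
        s_po[top] = 0.0
        s_pi[top] = f
        s_parent[top] = level
        top += 1
        s_node[top] = hot
        s_level[top] = level + 1
        s_plen[top] = plen
        s_pz[top] = hz * iz
        s_po[top] = io
        s_pi[top] = f
        s_parent[top] = level
        top += 1


@njit(cache=False)
def _shap_tree_batch(cl, cr, feat, thr, val, w, X, phi, max_depth):
    for i in range(X.shape[0]):
        _shap_one(cl, cr, feat, thr, val, w, X[i], phi[i], max_depth)


def tree_arrays(tree, positive_class_index: int = 1):
    """Extract flat arrays (and leaf positive-class probabilities) from a
    fitted sklearn decision tree."""
    t = tree.tree_
    value = t.value[:, 0, :]
    totals = value.sum(axis=1)
    prob = value[:, positive_class_index] / np.where(totals > 0, totals, 1.0)
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        prob.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def forest_shap_values(model, X, check_additivity: bool = True):
    """Shapley attributions for the positive class of a fitted forest.

    Returns ``(phi, base)`` where ``phi`` is (n_samples, n_features) and
    ``base`` is the expected model output (mean over trees of the root
    positive-class fraction).  Works for RandomForestClassifier and single
    DecisionTreeClassifier models.
    """
    if hasattr(model, "estimators_"):
        trees = model.estimators_
    elif hasattr(model, "tree_"):
        trees = [model]
    else:
        raise UnsupportedModelError(
            f"{type(model).__name__} is not a supported tree ensemble"
        )
    pos = int(np.where(np.asarray(model.classes_) == 1)[0][0]) if hasattr(
        model, "classes_") else 1
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    tmp = np.zeros_like(phi)
    for tree in trees:
        cl, cr, feat, thr, val, w, md = tree_arrays(tree, pos)
        tmp[:] = 0.0
        _shap_tree_batch(cl, cr, feat, thr, val, w, X, tmp, md)
        phi += tmp
        base += val[0]
    phi /= len(trees)
    base /= len(trees)
    if check_additivity:
        pred = model.predict_proba(X)[:, pos]
        err = np.abs(phi.sum(axis=1) + base - pred).max()
        if err > 1e-6:
            raise AssertionError(
                f"Shapley additivity violated (max error {err:.2e})"
            )
    return phi, float(base)
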