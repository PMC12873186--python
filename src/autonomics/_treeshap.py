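"""Exact Shapley attributions for tree ensembles.

For a single decision tree, the conditional expectation of the prediction
given a feature coalition S is computed by the standard cover-weighted
traversal: at a split on a feature in S the sample's branch is followed;
otherwise both children are visited weighted by their training cover.
This is the value function of path-dependent tree Shapley attribution.
The Shapley value of each feature is then assembled exactly from the
2^M coalition values

    phi_i = sum_{S not containing i} |S|! (M-|S|-1)! / M! * (v(S+i) - v(S)),

and averaged over the ensemble (the ensemble prediction is linear in the
trees, so Shapley values add).  Exactness makes the efficiency property

    sum_i phi_i + E[f] = f(x)

hold to machine precision, which the test suite asserts.

Complexity is O(2^M * nodes) per sample and tree — exact and fast for the
small physiological feature panels this package targets (M <= 15 enforced).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_shap", "tree_coalition_values"]

_MAX_FEATURES = 15


@njit(cache=True)
def _subset_values(children_left, children_right, feature, threshold,
                   values, cover, x, m):
    """v(S) for every coalition bitmask S (length 2^m) for one tree."""
    nv = 1 << m
    out = np.empty(nv)
    n_nodes = children_left.size
    stack_node = np.empty(n_nodes * 2, dtype=np.int64)
    stack_w = np.empty(n_nodes * 2)
    for s in range(nv):
        total = 0.0
        top = 0
        stack_node[0] = 0
        stack_w[0] = 1.0
        top = 1
        while top > 0:
            top -= 1
            node = stack_node[top]
            w = stack_w[top]
            left = children_left[node]
            if left == -1:  # leaf
                total += w * values[node]
                continue
            right = children_right[node]
            f = feature[node]
            if (s >> f) & 1:
                nxt = left if x[f] <= threshold[node] else right
                stack_node[top] = nxt
                stack_w[top] = w
                top += 1
            else:
                c = cover[node]
                stack_node[top] = left
                stack_w[top] = w * cover[left] / c
                top += 1
                stack_node[top] = right
                stack_w[top] = w * cover[right] / c
                top += 1
        out[s] = total
    return out


@njit(cache=True)
def _phi_from_values(v, m, weights):
    """Exact Shapley combination of the 2^m coalition values."""
    phi = np.zeros(m)
    nv = 1 << m
    for s in range(nv):
        # popcount
        c = 0
        t = s
        while t:
            t &= t - 1
            c += 1
        for i in range(m):
            if not (s >> i) & 1:
                phi[i] += weights[c] * (v[s | (1 << i)] - v[s])
    return phi


def _shapley_weights(m):
    from math import factorial

    return np.array([factorial(k) * factorial(m - k - 1) / factorial(m)
                     for k in range(m)])


def _tree_arrays(tree):
    """Extract flat arrays from an sklearn tree; values = P(class 1)."""
    t = tree.tree_
    val = t.value.reshape(t.node_count, -1)
    if val.shape[1] == 2:  # classifier: normalized class-1 fraction
        out_val = val[:, 1] / np.maximum(val.sum(axis=1), 1e-300)
    else:
        out_val = val[:, 0]
    return (t.children_left.astype(np.int64), t.children_right.astype(np.int64),
            t.feature.astype(np.int64), t.threshold.astype(np.float64),
            np.ascontiguousarray(out_val, dtype=np.float64),
            t.weighted_n_node_samples.astype(np.float64))


def tree_coalition_values(tree, x, m):
    """Coalition value table v(S) of one fitted tree at sample ``x``."""
    cl, cr, feat, thr, val, cov = _tree_arrays(tree)
    return _subset_values(cl, cr, feat, thr, val, cov,
                          np.ascontiguousarray(x, dtype=np.float64), m)


def forest_shap(forest, X):
    """Exact Shapley attributions of a fitted random forest's P(class 1).

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features)
    and ``base`` the per-sample expected value, such that
    ``phi.sum(1) + base == forest.predict_proba(X)[:, 1]`` exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    n, m = X.shape
    if m > _MAX_FEATURES:
        raise ValueError(
            f"exact Shapley enumeration supports at most {_MAX_FEATURES} features, got {m}")
    weights = _shapley_weights(m)
    trees = [_tree_arrays(est) for est in forest.estimators_]
    phi = np.zeros((n, m))
    base = np.zeros(n)
    for cl, cr, feat, thr, val, cov in trees:
        for j in range(n):
            v = _subset_values(cl, cr, feat, thr, val, cov, X[j], m)
            phi[j] += _phi_from_values(v, m, weights)
            base[j] += v[0]
    k = len(trees)
    return phi / k, base / k
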