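"""Numba kernels for the resampling-heavy inner loops.

The stability-selection loop refits a random forest (Boruta's importance
learner) and an elastic-net logistic path hundreds of times per Monte-Carlo
split on cohorts of ~40 training samples. At that size the per-call overhead
of generic estimators dominates, so the two inner-loop learners are compiled
here: a gini CART forest with impurity importances and a glmnet-style
coordinate-descent elastic-net logistic path. Both are cross-checked against
scikit-learn in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _node_gini(n0, n1):
    n = n0 + n1
    if n == 0:
        return 0.0
    p0 = n0 / n
    p1 = n1 / n
    return 1.0 - p0 * p0 - p1 * p1


@njit(cache=True)
def _grow_tree(X, y, buf, feats, mtry, max_depth, importances):
    """Grow one CART tree in place; accumulate weighted impurity decreases.

    ``buf`` holds the bootstrap sample indices and is partitioned in place as
    nodes split, sklearn-style. Importances are accumulated un-normalized and
    normalized by the caller.
    """
    n_total = buf.shape[0]
    p = X.shape[1]
    # explicit stack: (lo, hi, depth)
    stack_lo = np.empty(4 * n_total + 8, dtype=np.int64)
    stack_hi = np.empty(4 * n_total + 8, dtype=np.int64)
    stack_d = np.empty(4 * n_total + 8, dtype=np.int64)
    top = 0
    stack_lo[top], stack_hi[top], stack_d[top] = 0, n_total, 0
    top += 1
    tree_imp = np.zeros(p)
    while top > 0:
        top -= 1
        lo, hi, depth = stack_lo[top], stack_hi[top], stack_d[top]
        nn = hi - lo
        n1 = 0
        for i in range(lo, hi):
            n1 += y[buf[i]]
        if nn < 2 or n1 == 0 or n1 == nn or depth >= max_depth:
            continue
        parent_gini = _node_gini(nn - n1, n1)
        # sample mtry distinct candidate features (partial Fisher-Yates)
        for i in range(mtry):
            j = i + np.random.randint(p - i)
            feats[i], feats[j] = feats[j], feats[i]
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for fi in range(mtry):
            f = feats[fi]
            vals = np.empty(nn)
            labs = np.empty(nn, dtype=np.int64)
            for i in range(nn):
                vals[i] = X[buf[lo + i], f]
                labs[i] = y[buf[lo + i]]
            order = np.argsort(vals, kind="mergesort")
            left1 = 0
            for k in range(nn - 1):
                left1 += labs[order[k]]
                if vals[order[k + 1]] <= vals[order[k]]:
                    continue  # not a valid split point (tied values)
                nl = k + 1
                nr = nn - nl
                g = (
                    parent_gini
                    - (nl / nn) * _node_gini(nl - left1, left1)
                    - (nr / nn) * _node_gini(nr - (n1 - left1), n1 - left1)
                )
                if g > best_gain:
                    best_gain = g
                    best_f = f
                    best_thr = 0.5 * (vals[order[k]] + vals[order[k + 1]])
        if best_f < 0:
            continue
        tree_imp[best_f] += (nn / n_total) * best_gain
        # partition buf[lo:hi] on best feature/threshold
        i, j = lo, hi - 1
        while i <= j:
            if X[buf[i], best_f] <= best_thr:
                i += 1
            else:
                buf[i], buf[j] = buf[j], buf[i]
                j -= 1
        mid = i
        if mid > lo and mid < hi:
            stack_lo[top], stack_hi[top], stack_d[top] = lo, mid, depth + 1
            top += 1
            stack_lo[top], stack_hi[top], stack_d[top] = mid, hi, depth + 1
            top += 1
    s = tree_imp.sum()
    if s > 0.0:
        for j in range(p):
            importances[j] += tree_imp[j] / s


@njit(cache=True)
def rf_importances(X, y, n_trees, mtry, max_depth, seed):
    """Gini impurity importances of a bootstrap CART forest (binary labels).

    Per-tree importances are normalized to sum to one and averaged, matching
    sklearn's ``feature_importances_`` convention.
    """
    np.random.seed(seed)
    n, p = X.shape
    importances = np.zeros(p)
    buf = np.empty(n, dtype=np.int64)
    feats = np.arange(p)
    for _ in range(n_trees):
        for i in range(n):
            buf[i] = np.random.randint(n)
        _grow_tree(X, y, buf, feats, mtry, max_depth, importances)
    return importances / n_trees


@njit(cache=True)
def _grow_tree_stored(X, y, buf, feats, mtry, max_depth,
                      node_feat, node_thr, node_left, node_right, node_prob):
    """Grow one CART tree and store its structure for later traversal.

    Returns the number of nodes. Leaves have ``node_feat == -1`` and carry
    the class-1 fraction in ``node_prob``.
    """
    n_total = buf.shape[0]
    p = X.shape[1]
    stack_lo = np.empty(4 * n_total + 8, dtype=np.int64)
    stack_hi = np.empty(4 * n_total + 8, dtype=np.int64)
    stack_d = np.empty(4 * n_total + 8, dtype=np.int64)
    stack_id = np.empty(4 * n_total + 8, dtype=np.int64)
    top = 0
    stack_lo[top], stack_hi[top], stack_d[top], stack_id[top] = 0, n_total, 0, 0
    top += 1
    n_nodes = 1
    while top > 0:
        top -= 1
        lo, hi, depth, nid = stack_lo[top], stack_hi[top], stack_d[top], stack_id[top]
        nn = hi - lo
        n1 = 0
        for i in range(lo, hi):
            n1 += y[buf[i]]
        node_feat[nid] = -1
        node_prob[nid] = n1 / nn
        if nn < 2 or n1 == 0 or n1 == nn or depth >= max_depth:
            continue
        parent_gini = _node_gini(nn - n1, n1)
        for i in range(mtry):
            j = i + np.random.randint(p - i)
            feats[i], feats[j] = feats[j], feats[i]
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for fi in range(mtry):
            f = feats[fi]
            vals = np.empty(nn)
            labs = np.empty(nn, dtype=np.int64)
            for i in range(nn):
                vals[i] = X[buf[lo + i], f]
                labs[i] = y[buf[lo + i]]
            order = np.argsort(vals, kind="mergesort")
            left1 = 0
            for k in range(nn - 1):
                left1 += labs[order[k]]
                if vals[order[k + 1]] <= vals[order[k]]:
                    continue
                nl = k + 1
                nr = nn - nl
                g = (
                    parent_gini
                    - (nl / nn) * _node_gini(nl - left1, left1)
                    - (nr / nn) * _node_gini(nr - (n1 - left1), n1 - left1)
                )
                if g > best_gain:
                    best_gain = g
                    best_f = f
                    best_thr = 0.5 * (vals[order[k]] + vals[order[k + 1]])
        if best_f < 0:
            continue
        i, j = lo, hi - 1
        while i <= j:
            if X[buf[i], best_f] <= best_thr:
                i += 1
            else:
                buf[i], buf[j] = buf[j], buf[i]
                j -= 1
        mid = i
        if mid == lo or mid == hi:
            continue
        node_feat[nid] = best_f
        node_thr[nid] = best_thr
        node_left[nid] = n_nodes
        node_right[nid] = n_nodes + 1
        stack_lo[top], stack_hi[top], stack_d[top], stack_id[top] = lo, mid, depth + 1, n_nodes
        top += 1
        stack_lo[top], stack_hi[top], stack_d[top], stack_id[top] = mid, hi, depth + 1, n_nodes + 1
        top += 1
        n_nodes += 2
    return n_nodes


@njit(cache=True)
def _tree_predict_one(X, row, swap_feat, swap_val,
                      node_feat, node_thr, node_left, node_right, node_prob):
    """Traverse a stored tree for one sample, optionally overriding one
    feature's value (for permutation importance)."""
    nid = 0
    while node_feat[nid] >= 0:
        f = node_feat[nid]
        v = swap_val if f == swap_feat else X[row, f]
        nid = node_left[nid] if v <= node_thr[nid] else node_right[nid]
    return node_prob[nid]


@njit(cache=True)
def rf_oob_permutation_z(X, y, n_trees, mtry, max_depth, seed):
    """OOB permutation importance Z-scores of a bootstrap CART forest.

    Per tree, each feature used by the tree has its out-of-bag values
    permuted and the increase in OOB misclassification recorded; the score
    is the across-tree mean divided by its standard error (features never
    used score zero), the convention of permutation-importance Boruta.
    """
    np.random.seed(seed)
    n, p = X.shape
    imp_sum = np.zeros(p)
    imp_sumsq = np.zeros(p)
    buf = np.empty(n, dtype=np.int64)
    feats = np.arange(p)
    max_nodes = 4 * n + 8
    node_feat = np.empty(max_nodes, dtype=np.int64)
    node_thr = np.empty(max_nodes)
    node_left = np.empty(max_nodes, dtype=np.int64)
    node_right = np.empty(max_nodes, dtype=np.int64)
    node_prob = np.empty(max_nodes)
    inbag = np.empty(n, dtype=np.int64)
    oob = np.empty(n, dtype=np.int64)
    used = np.empty(p, dtype=np.int64)
    for _t in range(n_trees):
        inbag[:] = 0
        for i in range(n):
            b = np.random.randint(n)
            buf[i] = b
            inbag[b] = 1
        n_nodes = _grow_tree_stored(X, y, buf, feats, mtry, max_depth,
                                    node_feat, node_thr, node_left,
                                    node_right, node_prob)
        n_oob = 0
        for i in range(n):
            if inbag[i] == 0:
                oob[n_oob] = i
                n_oob += 1
        if n_oob == 0:
            continue
        used[:] = 0
        for nid in range(n_nodes):
            if node_feat[nid] >= 0:
                used[node_feat[nid]] = 1
        base_err = 0.0
        for k in range(n_oob):
            pr = _tree_predict_one(X, oob[k], -1, 0.0, node_feat, node_thr,
                                   node_left, node_right, node_prob)
            if (pr > 0.5) != (y[oob[k]] == 1):
                base_err += 1.0
        base_err /= n_oob
        perm = np.empty(n_oob, dtype=np.int64)
        for j in range(p):
            if used[j] == 0:
                continue
            for k in range(n_oob):
                perm[k] = k
            for k in range(n_oob - 1, 0, -1):
                r = np.random.randint(k + 1)
                perm[k], perm[r] = perm[r], perm[k]
            err = 0.0
            for k in range(n_oob):
                row = oob[k]
                swap = X[oob[perm[k]], j]
                pr = _tree_predict_one(X, row, j, swap, node_feat, node_thr,
                                       node_left, node_right, node_prob)
                if (pr > 0.5) != (y[row] == 1):
                    err += 1.0
            d = err / n_oob - base_err
            imp_sum[j] += d
            imp_sumsq[j] += d * d
    mean = imp_sum / n_trees
    var = imp_sumsq / n_trees - mean * mean
    z = np.zeros(p)
    for j in range(p):
        if var[j] > 1e-18:
            z[j] = mean[j] / np.sqrt(var[j] / n_trees)
        elif mean[j] != 0.0:
            z[j] = np.sign(mean[j]) * 1e6
    return z


@njit(cache=True)
def _soft_threshold(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def enet_logistic_path(X, y, lambdas, alpha, max_outer, max_inner, tol):
    """Elastic-net penalized logistic regression along a penalty path.

    Minimizes ``(1/n) sum(logloss) + lam * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)``
    (intercept unpenalized) by IRLS with inner coordinate descent, warm-started
    from the previous (larger) penalty, glmnet-style. Returns (coefs, intercepts)
    with one row per lambda.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("labels must contain both classes")
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    for li in range(n_lam):
        lam = lambdas[li]
        for _outer in range(max_outer):
            pr = 1.0 / (1.0 + np.exp(-eta))
            for i in range(n):
                if pr[i] < 1e-5:
                    pr[i] = 1e-5
                elif pr[i] > 1.0 - 1e-5:
                    pr[i] = 1.0 - 1e-5
            w = pr * (1.0 - pr)
            r = (y - pr) / w  # working residual (z - eta)
            beta_old_outer = beta.copy()
            b0_old_outer = b0
            for _sweep in range(max_inner):
                max_delta = 0.0
                wsum = w.sum()
                d0 = (w * r).sum() / wsum
                if d0 != 0.0:
                    b0 += d0
                    r -= d0
                    if abs(d0) > max_delta:
                        max_delta = abs(d0)
                for j in range(p):
                    vj = 0.0
                    rho = 0.0
                    for i in range(n):
                        wx = w[i] * X[i, j]
                        vj += wx * X[i, j]
                        rho += wx * r[i]
                    vj /= n
                    rho = rho / n + vj * beta[j]
                    bj = _soft_threshold(rho, lam * alpha) / (vj + lam * (1.0 - alpha))
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        for i in range(n):
                            r[i] -= d * X[i, j]
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                if max_delta < tol:
                    break
            # refresh linear predictor and check outer convergence
            eta = X @ beta + b0
            delta = abs(b0 - b0_old_outer)
            for j in range(p):
                dj = abs(beta[j] - beta_old_outer[j])
                if dj > delta:
                    delta = dj
            if delta < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts
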