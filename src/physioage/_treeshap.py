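"""Interventional tree-Shapley engine for XGBoost ensembles.

Computes exact Shapley values of a tree ensemble with respect to an
explicit background (reference) population: the value of a coalition S
is the model output with features in S taken from the explained row and
the rest from a background row, averaged over the background. For a
single (row, background) pair and one tree the Shapley values have a
closed form — each leaf reachable by a mixed path contributes
``v * (a-1)! b! / (a+b)!`` to the features forced to the row's side and
``-v * a! (b-1)! / (a+b)!`` to those forced to the background's side,
where ``a`` and ``b`` count the unique diverging features on the path.
Averaging over pairs and summing over trees is exact and satisfies the
efficiency axiom: base + sum(phi) equals the model prediction, with the
base equal to the mean prediction over the background.

Thresholds are compared in float32, mirroring XGBoost's internal split
evaluation, so leaf routing agrees with ``Booster.predict``; leaf values
are accumulated in float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_MAXD = 128  # generous bound on unique diverging features along a path


def extract_trees(booster, feature_names: list[str]):
    """Flatten an XGBoost booster into parallel node arrays.

    Returns (feat, thr, left, right, miss, val, offsets): node-indexed
    arrays concatenated over trees, with ``feat = -1`` marking leaves and
    ``offsets`` delimiting each tree's node slice.
    """
    df = booster.trees_to_dataframe()
    name_to_idx = {n: i for i, n in enumerate(feature_names)}
    feat_l, thr_l, left_l, right_l, miss_l, val_l = [], [], [], [], [], []
    offsets = [0]
    for _, g in df.groupby("Tree", sort=True):
        g = g.sort_values("Node")
        local = {node_id: k for k, node_id in enumerate(g["ID"])}
        base = offsets[-1]
        for row in g.itertuples():
            if row.Feature == "Leaf":
                feat_l.append(-1)
                thr_l.append(0.0)
                left_l.append(-1)
                right_l.append(-1)
                miss_l.append(-1)
                val_l.append(row.Gain)
            else:
                f = name_to_idx.get(row.Feature)
                if f is None:  # dumps may use f<idx> labels
                    f = int(str(row.Feature).lstrip("f"))
                feat_l.append(f)
                thr_l.append(np.float32(row.Split))
                left_l.append(base + local[row.Yes])
                right_l.append(base + local[row.No])
                miss_l.append(base + local[row.Missing])
                val_l.append(0.0)
        offsets.append(base + len(g))
    return (
        np.asarray(feat_l, dtype=np.int64),
        np.asarray(thr_l, dtype=np.float32),
        np.asarray(left_l, dtype=np.int64),
        np.asarray(right_l, dtype=np.int64),
        np.asarray(miss_l, dtype=np.int64),
        np.asarray(val_l, dtype=np.float64),
        np.asarray(offsets, dtype=np.int64),
    )


@njit(cache=True)
def _routes(feat, thr, left, right, miss, X):
    """Child index each row takes at every internal node (-1 at leaves)."""
    n = X.shape[0]
    nn = feat.shape[0]
    R = np.full((n, nn), -1, dtype=np.int32)
    for node in range(nn):
        f = feat[node]
        if f < 0:
            continue
        l, r, m, t = left[node], right[node], miss[node], thr[node]
        for i in range(n):
            v = X[i, f]
            if np.isnan(v):
                R[i, node] = m
            elif np.float32(v) < t:
                R[i, node] = l
            else:
                R[i, node] = r
    return R


@njit(cache=True)
def _pair_shap(feat, val, root, rx, rz, phi, state,
               path_f, path_s, stack_n, stack_act, stack_aux, fact):
    """Add one (row, background)-pair Shapley contribution of one tree to phi.

    ``rx`` / ``rz`` are the precomputed routing rows of the explained and
    background individuals.
    """
    stack_n[0] = root
    stack_act[0] = 0
    stack_aux[0] = 0
    sp = 1
    pp = 0
    a = 0
    b = 0
    while sp > 0:
        sp -= 1
        node = stack_n[sp]
        act = stack_act[sp]
        if act == 1:  # flip feature aux to the background side, then visit
            aux = stack_aux[sp]
            state[aux] = 2
            path_s[pp - 1] = 2
            a -= 1
            b += 1
        elif act == 2:  # unwind a diverging feature (stored in node slot)
            state[node] = 0
            b -= 1
            pp -= 1
            continue
        f = feat[node]
        if f < 0:  # leaf
            tot = a + b
            if tot > 0:
                v = val[node]
                wpos = 0.0
                wneg = 0.0
                if a > 0:
                    wpos = fact[a - 1] * fact[b] / fact[tot] * v
                if b > 0:
                    wneg = fact[a] * fact[b - 1] / fact[tot] * v
                for q in range(pp):
                    if path_s[q] == 1:
                        phi[path_f[q]] += wpos
                    else:
                        phi[path_f[q]] -= wneg
            continue
        cx = rx[node]
        cz = rz[node]
        s = state[f]
        if s == 1:
            stack_n[sp] = cx
            stack_act[sp] = 0
            sp += 1
        elif s == 2:
            stack_n[sp] = cz
            stack_act[sp] = 0
            sp += 1
        elif cx == cz:
            stack_n[sp] = cx
            stack_act[sp] = 0
            sp += 1
        else:
            stack_n[sp] = f  # unwind marker
            stack_act[sp] = 2
            stack_n[sp + 1] = cz  # background-side branch, after the flip
            stack_act[sp + 1] = 1
            stack_aux[sp + 1] = f
            stack_n[sp + 2] = cx  # row-side branch, visited first
            stack_act[sp + 2] = 0
            sp += 3
            state[f] = 1
            path_f[pp] = f
            path_s[pp] = 1
            pp += 1
            a += 1


@njit(cache=True, parallel=True)
def _shap_all(feat, val, offsets, RX, RZ, phi):
    n = RX.shape[0]
    m = RZ.shape[0]
    p = phi.shape[1]
    ntree = offsets.shape[0] - 1
    fact = np.empty(_MAXD, dtype=np.float64)
    fact[0] = 1.0
    for k in range(1, _MAXD):
        fact[k] = fact[k - 1] * k
    for i in prange(n):
        state = np.zeros(p, dtype=np.int8)
        path_f = np.empty(_MAXD, dtype=np.int64)
        path_s = np.empty(_MAXD, dtype=np.int8)
        stack_n = np.empty(4 * _MAXD, dtype=np.int64)
        stack_act = np.empty(4 * _MAXD, dtype=np.int8)
        stack_aux = np.empty(4 * _MAXD, dtype=np.int64)
        row_phi = phi[i]
        rx = RX[i]
        for j in range(m):
            rz = RZ[j]
            for t in range(ntree):
                _pair_shap(feat, val, offsets[t], rx, rz, row_phi, state,
                           path_f, path_s, stack_n, stack_act, stack_aux, fact)
        for q in range(p):
            row_phi[q] /= m


@njit(cache=True)
def _predict(feat, val, offsets, R, base_score):
    n = R.shape[0]
    ntree = offsets.shape[0] - 1
    out = np.full(n, base_score, dtype=np.float64)
    for i in range(n):
        for t in range(ntree):
            node = offsets[t]
            while feat[node] >= 0:
                node = R[i, node]
            out[i] += val[node]
    return out


def shap_values(trees, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Interventional Shapley values of every row of ``X`` against
    background ``Z``; shape (n_rows, n_features), float64 years."""
    feat, thr, left, right, miss, val, offsets = trees
    X = np.ascontiguousarray(X, dtype=np.float64)
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    phi = np.zeros(X.shape, dtype=np.float64)
    if X.size and Z.size:
        RX = _routes(feat, thr, left, right, miss, X)
        RZ = RX if Z is X or (Z.shape == X.shape and Z.base is X) else _routes(feat, thr, left, right, miss, Z)
        _shap_all(feat, val, offsets, RX, RZ, phi)
    return phi


def predict_values(trees, X: np.ndarray, base_score: float) -> np.ndarray:
    """Float64 ensemble predictions with the same leaf routing as
    :func:`shap_values` (used for exact base values and additivity)."""
    feat, thr, left, right, miss, val, offsets = trees
    X = np.ascontiguousarray(X, dtype=np.float64)
    R = _routes(feat, thr, left, right, miss, X)
    return _predict(feat, val, offsets, R, base_score)
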