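"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity from its mathematical definition by a
route deliberately different from the package implementation.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(values) -> float:
    """Dip by direct optimization over unimodal CDFs.

    For each candidate mode x_k (an atom is allowed at the mode, which is
    the only point where a unimodal CDF may jump), solve a linear program:
    minimize eps such that a function G exists with
      * |G - F_n| <= eps in sup norm (constraints at every data point,
        including left limits),
      * G nondecreasing,
      * G convex on the points left of the mode and concave right of it.
    The dip is the minimum over modes.  Modes interior to a data segment
    never beat the best data-point mode (the segment's shape constraint
    relaxation is equivalent to one of the two neighbouring point modes).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if np.unique(x).size != n:
        raise ValueError("oracle requires distinct values")
    best = np.inf
    for k in range(1, n + 1):  # mode at x_k (1-based)
        # variables: g_1..g_n (left-limit value at the mode index), h (right
        # value at the mode), eps
        nv = n + 2
        ih = n
        ie = n + 1
        A, b = [], []

        def le(coefs, rhs):  # coefs: {var: coef} for "<= rhs"
            row = np.zeros(nv)
            for v, c in coefs.items():
                row[v] = c
            A.append(row)
            b.append(rhs)

        # band constraints
        for i in range(1, n + 1):
            gi = i - 1
            if i == k:
                le({gi: 1, ie: -1}, (i - 1) / n)
                le({gi: -1, ie: -1}, -(i - 1) / n)
                le({ih: 1, ie: -1}, i / n)
                le({ih: -1, ie: -1}, -i / n)
            else:
                le({gi: 1, ie: -1}, (i - 1) / n)
                le({gi: -1, ie: -1}, -i / n)
        # monotonicity along g_1..g_k, h, g_{k+1}..g_n
        seq = list(range(k)) + [ih] + list(range(k, n))
        for a_, b_ in zip(seq[:-1], seq[1:]):
            le({a_: 1, b_: -1}, 0.0)
        # convexity left of mode: slopes nondecreasing over (x_1,g_1)..(x_k,g_k)
        pts_l = [(x[i - 1], i - 1) for i in range(1, k + 1)]
        for (x0, v0), (x1, v1), (x2, v2) in zip(pts_l, pts_l[1:], pts_l[2:]):
            # (v1-v0)/(x1-x0) <= (v2-v1)/(x2-x1)
            d0, d1 = x1 - x0, x2 - x1
            le({v0: -d1, v1: (d0 + d1), v2: -d0}, 0.0)
        # concavity right of mode: slopes nonincreasing over (x_k,h),(x_{k+1},g_{k+1}),..
        pts_r = [(x[k - 1], ih)] + [(x[i - 1], i - 1) for i in range(k + 1, n + 1)]
        for (x0, v0), (x1, v1), (x2, v2) in zip(pts_r, pts_r[1:], pts_r[2:]):
            d0, d1 = x1 - x0, x2 - x1
            le({v0: d1, v1: -(d0 + d1), v2: d0}, 0.0)

        c = np.zeros(nv)
        c[ie] = 1.0
        bounds = [(0.0, 1.0)] * (n + 1) + [(0.0, 1.0)]
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                      method="highs")
        if not res.success:
            raise RuntimeError(f"LP failed for mode {k}: {res.message}")
        best = min(best, res.fun)
    return float(best)


# ---------------------------------------------------------------------------
# weighted average family size: naive double loop

def naive_weighted_size(counts, scheme="inv_max"):
    """Direct per-species evaluation of the weighted-size formula with
    explicit Python loops; counts is a families x species 2-D array."""
    counts = np.asarray(counts, dtype=float)
    n_fam, n_sp = counts.shape
    denoms = []
    for i in range(n_fam):
        row = counts[i]
        if scheme == "inv_max":
            d = max(row)
        elif scheme == "inv_mean":
            d = sum(row) / n_sp
        elif scheme == "inv_median":
            d = float(np.median(row))
        else:
            raise ValueError(scheme)
        denoms.append(d)
    used = [i for i in range(n_fam) if denoms[i] > 0]
    mean_max = sum(denoms[i] for i in used) / len(used)
    out = []
    for s in range(n_sp):
        acc = 0.0
        for i in used:
            acc += counts[i, s] * (1.0 / denoms[i])
        out.append(acc / len(used) * mean_max)
    return np.array(out)


# ---------------------------------------------------------------------------
# PIC via generalized least squares

def pic_gls(tree, trait):
    """Contrasts recomputed by matrix algebra: at each internal node the
    GLS (BLUE) estimates of its two children's states are differenced and
    standardized by pendant lengths plus estimation variances.

    Independent of the pruning recursion: subtree ancestral states come
    from inverting the within-subtree tip covariance matrix."""

    def subtree_estimate(node):
        leaves = [l for l in node.leaf_iter()]
        labs = [l.taxon.label for l in leaves]
        x = np.array([trait[l] for l in labs], dtype=float)
        if len(leaves) == 1:
            return x[0], 0.0
        # covariance of tips below `node`: shared path length to the node
        k = len(leaves)
        V = np.zeros((k, k))
        paths = []
        for leaf in leaves:
            path = []
            nd = leaf
            while nd is not node:
                path.append(nd)
                nd = nd.parent_node
            paths.append(path)
        for i in range(k):
            for j in range(k):
                shared = {id(n) for n in paths[i]} & {id(n) for n in paths[j]}
                V[i, j] = sum(n.edge.length for n in paths[i]
                              if id(n) in shared)
        Vi = np.linalg.inv(V)
        one = np.ones(k)
        denom = one @ Vi @ one
        return (one @ Vi @ x) / denom, 1.0 / denom

    contrasts = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        assert len(kids) == 2
        (ma, va), (mb, vb) = subtree_estimate(kids[0]), subtree_estimate(kids[1])
        ba = kids[0].edge.length + va
        bb = kids[1].edge.length + vb
        contrasts.append((ma - mb) / np.sqrt(ba + bb))
    return np.array(contrasts)


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive enumeration

def fitch_exhaustive(node, presence):
    """State set at `node` = argmin over root states of the minimal number
    of changes over all labelings of the subtree below `node`."""
    internals = [n for n in node.postorder_iter() if not n.is_leaf()]
    leaves = [n for n in node.leaf_iter()]
    best = {0: np.inf, 1: np.inf}
    for assign in itertools.product((0, 1), repeat=len(internals)):
        lab = {id(n): s for n, s in zip(internals, assign)}
        for l in leaves:
            lab[id(l)] = int(presence[l.taxon.label])
        changes = 0
        for n in node.postorder_iter():
            if n is node:
                continue
            changes += lab[id(n)] != lab[id(n.parent_node)]
        root_state = lab[id(node)]
        best[root_state] = min(best[root_state], changes)
    m = min(best.values())
    return frozenset(s for s, c in best.items() if c == m)


def all_rooted_topologies(labels):
    """Yield every rooted binary topology (as nested tuples) on `labels`."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for size in range(0, len(rest)):
        for combo in itertools.combinations(rest, size):
            left_labels = (first,) + combo
            right_labels = tuple(l for l in rest if l not in combo)
            if not right_labels:
                continue
            for lt in all_rooted_topologies(left_labels):
                for rt in all_rooted_topologies(right_labels):
                    yield (lt, rt)


def topology_to_newick(top):
    if isinstance(top, str):
        return top + ":1"
    return "(" + ",".join(topology_to_newick(t) for t in top) + "):1"


# ---------------------------------------------------------------------------
# exact small-sample distributions by enumeration

def ks_exact_p(a, b):
    """Two-sample KS p-value by exhausting all assignments of the pooled
    sample to the two groups (no ties assumed)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))

    def ks_d(which_a):
        fa = np.cumsum(which_a) / n
        fb = np.cumsum(~which_a) / m
        return np.max(np.abs(fa - fb))

    mask = np.isin(np.argsort(np.argsort(np.concatenate([a, b]))), [])
    order = np.argsort(np.concatenate([a, b]), kind="mergesort")
    is_a_obs = np.zeros(n + m, bool)
    is_a_obs[:n] = True
    d_obs = ks_d(is_a_obs[order])
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        which = np.zeros(n + m, bool)
        which[list(combo)] = True
        total += 1
        if ks_d(which) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def ranksum_exact_p(a, b):
    """Two-sided rank-sum p by exhausting group assignments (no ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def hypergeom_tail(k, K, n, N):
    """P[X >= k] for X ~ Hypergeom(N, K, n), by direct summation of
    binomial-coefficient ratios (exact rational arithmetic)."""
    from math import comb
    from fractions import Fraction
    tot = Fraction(0)
    for j in range(k, min(K, n) + 1):
        tot += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(tot)


# ---------------------------------------------------------------------------
# DR statistic by recursive half-share allocation

def dr_recursive(tree):
    """Allocate each edge's length by halving the share at every split
    below it, then invert the per-tip totals."""
    es = {}

    def walk(node, inherited):
        length = node.edge.length or 0.0
        share = inherited + length
        if node.is_leaf():
            es[node.taxon.label] = share
            return
        for child in node.child_nodes():
            walk(child, share / 2.0)

    for child in tree.seed_node.child_nodes():
        walk(child, 0.0)
    return {k: 1.0 / v for k, v in es.items()}


# ---------------------------------------------------------------------------
# driver scan by naive recomputation

def naive_driver_scan(presence, loadings, coords, direction):
    """For each prefix size recompute the mean presence from scratch and
    correlate with the coordinates (Spearman); returns the rho profile."""
    from scipy import stats as st
    order = np.argsort(loadings, kind="mergesort")
    if direction == "descending":
        order = order[::-1]
    rhos = []
    for i in range(1, len(order) + 1):
        sub = presence[order[:i]]          # families x species
        avg = sub.mean(axis=0)
        if np.all(avg == avg[0]):
            rhos.append(np.nan)
            continue
        rhos.append(st.spearmanr(avg, coords)[0])
    return np.array(rhos)
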