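"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with explicit loops and first
principles (no shared code with the package) so it can serve as a second
opinion on small instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rank_with_ties(values):
    """Average ranks (1-based) with ties, by explicit counting."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def kw_h(values, groups):
    """Tie-corrected Kruskal-Wallis H by explicit summation."""
    N = len(values)
    ranks = rank_with_ties(values)
    labels = sorted(set(groups), key=str)
    h = 0.0
    for lab in labels:
        idx = [i for i, g in enumerate(groups) if g == lab]
        rbar = sum(ranks[i] for i in idx) / len(idx)
        h += len(idx) * rbar**2
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    # tie correction
    tie_sum = 0.0
    for v in set(values):
        t = sum(1 for w in values if w == v)
        if t > 1:
            tie_sum += t**3 - t
    corr = 1.0 - tie_sum / (N**3 - N)
    return 0.0 if corr == 0 else h / corr


def kw_exact_p(values, groups):
    """Exact permutation tail probability of H by enumerating all distinct
    assignments of the observed values to the group sizes."""
    h_obs = kw_h(values, groups)
    labels = sorted(set(groups), key=str)
    sizes = [sum(1 for g in groups if g == lab) for lab in labels]
    n = len(values)
    count = total = 0
    for perm in set(itertools.permutations(range(n))):
        groups_p = []
        pos = 0
        assigned = [None] * n
        for lab, size in zip(labels, sizes):
            for j in perm[pos:pos + size]:
                assigned[j] = lab
            pos += size
        key = tuple(assigned)
        groups_p = list(key)
        h = kw_h(values, groups_p)
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return count / total


def kw_exact_p_distinct(values, groups):
    """Same as kw_exact_p but over distinct label assignments only
    (equivalent probability; faster for repeated labels)."""
    h_obs = kw_h(values, groups)
    labels = sorted(set(groups), key=str)
    sizes = {lab: sum(1 for g in groups if g == lab) for lab in labels}
    n = len(values)
    count = total = 0
    seen = set()
    for perm in itertools.permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        h = kw_h(values, list(perm))
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return count / total


def pooled_t(a, b):
    """Two-sample pooled-variance t by explicit sums."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss = sum((x - m1) ** 2 for x in a) + sum((x - m2) ** 2 for x in b)
    sp2 = ss / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def anova_f(values, groups):
    """One-way ANOVA F from explicit between/within sums of squares."""
    labels = sorted(set(groups), key=str)
    grand = sum(values) / len(values)
    ssb = ssw = 0.0
    for lab in labels:
        grp = [v for v, g in zip(values, groups) if g == lab]
        m = sum(grp) / len(grp)
        ssb += len(grp) * (m - grand) ** 2
        ssw += sum((v - m) ** 2 for v in grp)
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    return (ssb / df1) / (ssw / df2)


def hypergeom_tail(M, K, n, x):
    """P(X >= x) for a hypergeometric urn by direct combinatorial summation."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, i) * math.comb(M - K, n - i)
        for i in range(x, min(K, n) + 1)
        if n - i <= M - K
    ) / total


def pearson_r(x, y):
    """Pearson correlation from explicit covariance sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def average_linkage_merges(d):
    """Brute-force average-linkage agglomeration of a small distance matrix.

    Returns the sorted multiset of merge heights.
    """
    d = np.asarray(d, dtype=float)
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, j in itertools.combinations(keys, 2):
            dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or dist < best[0] - 1e-15:
                best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[i] = clusters[i] + clusters.pop(j)
    return sorted(heights)


# ---------------------------------------------------------------------------
# SAM oracle (3 vs 3 two-class, full enumeration)


def sam_d(X, group1_idx, s0):
    """Moderated d per gene, explicit loops: (mean1 - mean0)/(s + s0)."""
    G, N = X.shape
    idx1 = sorted(group1_idx)
    idx0 = [i for i in range(N) if i not in idx1]
    n0, n1 = len(idx0), len(idx1)
    out = []
    for g in range(G):
        m0 = sum(X[g, i] for i in idx0) / n0
        m1 = sum(X[g, i] for i in idx1) / n1
        ss = sum((X[g, i] - m0) ** 2 for i in idx0) + sum((X[g, i] - m1) ** 2 for i in idx1)
        s = math.sqrt((1 / n0 + 1 / n1) * ss / (n0 + n1 - 2))
        out.append((m1 - m0) / (s + s0))
    return np.array(out)


def sam_enumeration(X, n1, s0):
    """All C(N, n1) label assignments -> per-assignment d vectors."""
    N = X.shape[1]
    return [sam_d(X, combo, s0) for combo in itertools.combinations(range(N), n1)]


def sam_fdr_at_delta(d_obs, perm_ds, delta, pi0=1.0):
    """FDR and called count at delta with the asymmetric origin-out cuts
    and the zero-median-falls-back-to-mean convention.  Explicit loops."""
    order = np.argsort(d_obs, kind="mergesort")
    ds = d_obs[order]
    dbar = np.mean([np.sort(p) for p in perm_ds], axis=0)
    diff = ds - dbar
    origin = int(np.searchsorted(ds, 0.0))
    cutup = math.inf
    for i in range(origin, len(ds)):
        if diff[i] >= delta:
            cutup = ds[i]
            break
    cutlow = -math.inf
    for i in range(origin - 1, -1, -1):
        if diff[i] <= -delta:
            cutlow = ds[i]
            break
    called = int(sum(1 for v in d_obs if v >= cutup or v <= cutlow))
    if called == 0:
        return 0.0, 0
    counts = [sum(1 for v in p if v >= cutup or v <= cutlow) for p in perm_ds]
    fp = float(np.median(counts))
    if fp == 0.0:
        fp = float(np.mean(counts))
    return fp * pi0 / called, called


def pca_eigen(X, n_components):
    """UV-scale then eigendecompose X'X; returns (scores, loadings, r2x)."""
    X = np.asarray(X, dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    w, v = np.linalg.eigh(Xs.T @ Xs)
    order = np.argsort(w)[::-1][:n_components]
    lam = w[order]
    loadings = v[:, order]
    scores = Xs @ loadings
    r2x = lam / (Xs**2).sum()
    return scores, loadings, r2x
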