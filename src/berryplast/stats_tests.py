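"""Per-gene statistical tests: Kruskal-Wallis, t, ANOVA, SAM, BH, hypergeometric.

The test statistics are computed in-package (vectorised across genes);
scipy.stats supplies only the reference distributions for tail
probabilities.  SAM (significance analysis of microarrays) follows the
original moderated-d formulation: d = r / (s + s0) with the fudge factor
s0 chosen to minimise the coefficient of variation of the d spread across
windows of s, an expected-order-statistic null from label permutations,
and a delta threshold calibrated to a target permutation FDR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .core_data import ExpressionMatrix, GeneSet

__all__ = [
    "GeneTestResult",
    "SamResult",
    "kruskal_wallis",
    "kruskal_wallis_many",
    "two_group_t_test",
    "t_test_many",
    "one_way_anova_bonferroni",
    "anova_many",
    "benjamini_hochberg",
    "hypergeometric_enrichment",
    "sam",
]


@dataclass
class GeneTestResult:
    """One gene's (or category's) test outcome."""

    gene_id: str | None
    statistic: float
    p_value: float
    q_value: float | None = None
    significant: bool | None = None
    flag: str | None = None


def _encode_groups(groups: Sequence) -> tuple[np.ndarray, list]:
    """Group labels -> integer codes in order of first appearance."""
    order: dict = {}
    for g in groups:
        order.setdefault(g, len(order))
    codes = np.array([order[g] for g in groups], dtype=int)
    return codes, list(order)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _kw_many(X: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected H and chi-square p for every row of X."""
    G, N = X.shape
    n_k = np.bincount(codes, minlength=n_groups)
    if (n_k == 0).any():
        empty = [i for i in range(n_groups) if n_k[i] == 0]
        raise ValueError(f"group(s) {empty} have no observations")
    R = rankdata(X, axis=1)
    ind = np.eye(n_groups)[codes]                       # N x K
    S = R @ ind                                          # rank sums per group
    H = 12.0 / (N * (N + 1)) * (S**2 / n_k).sum(axis=1) - 3.0 * (N + 1)
    # per-row tie correction
    C = np.ones(G)
    Xs = np.sort(X, axis=1)
    tied_rows = np.nonzero((np.diff(Xs, axis=1) == 0).any(axis=1))[0]
    for g in tied_rows:
        _, counts = np.unique(Xs[g], return_counts=True)
        t = counts[counts > 1].astype(float)
        C[g] = 1.0 - (t**3 - t).sum() / (N**3 - N)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(C > 0, H / np.where(C > 0, C, 1.0), 0.0)
    H = np.maximum(H, 0.0)
    p = np.where(C > 0, sps.chi2.sf(H, n_groups - 1), 1.0)
    p = np.where(H == 0, 1.0, p)
    return H, p


def kruskal_wallis_many(X: np.ndarray, groups: Sequence,
                        method: str = "chi2") -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Kruskal-Wallis over the rows of a genes x samples array.

    ``method="exact"`` replaces the chi-square p with the exact permutation
    tail probability (all distinct label assignments enumerated; intended
    for small per-group sizes where the chi-square approximation cannot
    reach small p, e.g. three groups of three).
    """
    codes, order = _encode_groups(groups)
    if len(order) < 2:
        raise ValueError("need >= 2 groups with observations")
    X = np.asarray(X, dtype=float)
    H, p = _kw_many(X, codes, len(order))
    if method == "exact":
        p = _kw_exact_many(X, codes, len(order), H)
    elif method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    return H, p


_MAX_EXACT_ASSIGNMENTS = 50_000


def _kw_exact_many(X: np.ndarray, codes: np.ndarray, K: int,
                   h_obs: np.ndarray) -> np.ndarray:
    """Exact KW tail probabilities by enumerating all label assignments."""
    from sympy.utilities.iterables import multiset_permutations

    N = X.shape[1]
    counts = np.bincount(codes, minlength=K).astype(float)
    total = math.factorial(N)
    for c in counts.astype(int):
        total //= math.factorial(int(c))
    if total > _MAX_EXACT_ASSIGNMENTS:
        raise ValueError(
            f"{total} distinct assignments exceed the exact-enumeration limit"
        )
    assigns = np.array(list(multiset_permutations(codes.tolist())), dtype=int)
    R = rankdata(X, axis=1)
    # per-row tie correction (depends only on the values, not the labels)
    C = np.ones(X.shape[0])
    Xs = np.sort(X, axis=1)
    for g in np.nonzero((np.diff(Xs, axis=1) == 0).any(axis=1))[0]:
        _, cnt = np.unique(Xs[g], return_counts=True)
        t = cnt[cnt > 1].astype(float)
        C[g] = 1.0 - (t**3 - t).sum() / (N**3 - N)
    ge = np.zeros(X.shape[0], dtype=np.int64)
    const = 12.0 / (N * (N + 1))
    for start in range(0, assigns.shape[0], 512):
        chunk = assigns[start:start + 512]
        onehot = np.eye(K)[chunk]                        # b x N x K
        S = np.einsum("gn,bnk->gbk", R, onehot)
        Hb = const * (S**2 / counts).sum(axis=2) - 3.0 * (N + 1)
        Hb = np.where(C[:, None] > 0, Hb / np.where(C[:, None] > 0, C[:, None], 1.0), 0.0)
        ge += (Hb >= h_obs[:, None] - 1e-9).sum(axis=1)
    return ge / assigns.shape[0]


def kruskal_wallis(values: Sequence[float], groups: Sequence,
                   method: str = "chi2", gene_id: str | None = None) -> GeneTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square (or small-n exact) p.

    ``method="exact"`` enumerates all distinct assignments of the observed
    values to the group sizes (feasible for ~<= 10 observations) and returns
    the exact permutation tail probability P(H >= H_obs).
    """
    x = np.asarray(values, dtype=float)
    codes, order = _encode_groups(groups)
    if len(order) < 2:
        raise ValueError("need >= 2 groups")
    H, p = _kw_many(x[None, :], codes, len(order))
    H, p = float(H[0]), float(p[0])
    if method == "exact":
        p = float(_kw_exact_many(x[None, :], codes, len(order), np.array([H]))[0])
    elif method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    return GeneTestResult(gene_id, H, p)


# ---------------------------------------------------------------------------
# t-test


def t_test_many(X: np.ndarray, groups: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per row; returns (t, p, zero_var_flag)."""
    codes, order = _encode_groups(groups)
    if len(order) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(order)}")
    X = np.asarray(X, dtype=float)
    a, b = X[:, codes == 0], X[:, codes == 1]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - m1[:, None]) ** 2).sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sp = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
    zero = sp == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (m1 - m2) / np.where(zero, 1.0, sp))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # zero pooled variance: equal means -> t=0,p=1; unequal -> p=0 (flagged)
    uneq = zero & (m1 != m2)
    p = np.where(zero, np.where(uneq, 0.0, 1.0), p)
    with np.errstate(invalid="ignore"):
        t = np.where(uneq, np.sign(m1 - m2) * np.inf, t)
    return t, p, zero


def two_group_t_test(values: Sequence[float], groups: Sequence,
                     gene_id: str | None = None) -> GeneTestResult:
    """Unpaired pooled-variance two-sample t-test, two-sided p."""
    t, p, zero = t_test_many(np.asarray(values, dtype=float)[None, :], groups)
    flag = "zero_pooled_variance" if zero[0] else None
    return GeneTestResult(gene_id, float(t[0]), float(p[0]), flag=flag)


# ---------------------------------------------------------------------------
# one-way ANOVA


def anova_many(X: np.ndarray, groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA F and p per row."""
    codes, order = _encode_groups(groups)
    K = len(order)
    if K < 2:
        raise ValueError("need >= 2 groups")
    X = np.asarray(X, dtype=float)
    G, N = X.shape
    n_k = np.bincount(codes, minlength=K)
    if (n_k < 2).any():
        raise ValueError("each group needs >= 2 values")
    ind = np.eye(K)[codes]
    M = (X @ ind) / n_k                                  # group means
    grand = X.mean(axis=1)
    ssb = (n_k * (M - grand[:, None]) ** 2).sum(axis=1)
    ssw = (X**2).sum(axis=1) - (n_k * M**2).sum(axis=1)
    ssw = np.maximum(ssw, 0.0)
    df1, df2 = K - 1, N - K
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    zero = ssw == 0
    F = np.where(zero & (ssb <= 1e-300), 0.0, F)
    p = np.where(np.isfinite(F), sps.f.sf(F, df1, df2), 0.0)
    p = np.where(F == 0, 1.0, p)
    return F, p


def one_way_anova_bonferroni(values: Sequence[float], groups: Sequence,
                             alpha: float = 0.01, n_tests: int = 1,
                             gene_id: str | None = None) -> GeneTestResult:
    """One-way ANOVA; significant iff p < alpha / n_tests (Bonferroni)."""
    F, p = anova_many(np.asarray(values, dtype=float)[None, :], groups)
    return GeneTestResult(gene_id, float(F[0]), float(p[0]),
                          significant=bool(p[0] < alpha / n_tests))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values (monotone in p-rank, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeometric_enrichment(
    study: GeneSet,
    universe: GeneSet,
    annotation: Mapping[str, Iterable[str]],
    threshold: float = 0.1,
) -> list[GeneTestResult]:
    """Upper-tail hypergeometric over-representation per category.

    ``annotation`` maps gene_id -> iterable of category labels; it may cover
    only a subset of the universe.  Categories with p < threshold are
    flagged over-represented (``significant``).
    """
    if not study.members <= universe.members:
        extra = sorted(study.members - universe.members)[:5]
        raise ValueError(f"study set is not contained in the universe (e.g. {extra})")
    M = len(universe)
    n = len(study)
    cat_universe: dict[str, set[str]] = {}
    for gene, cats in annotation.items():
        if gene in universe:
            for c in cats:
                cat_universe.setdefault(c, set()).add(gene)
    results = []
    for cat in sorted(cat_universe):
        members = cat_universe[cat]
        K = len(members)
        x = len(members & study.members)
        p = float(sps.hypergeom.sf(x - 1, M, K, n))
        p = min(p, 1.0)
        results.append(GeneTestResult(cat, float(x), p, significant=bool(p < threshold)))
    return results


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamResult:
    """Significance-analysis-of-microarrays outcome at the calibrated delta."""

    gene_ids: list[str]
    d: np.ndarray                    # observed d per gene (input order)
    d_expected: np.ndarray           # permutation-mean order statistics (ascending)
    delta: float
    n_permutations: int
    fdr: float                       # estimated FDR at `delta`
    significant: GeneSet
    s0: float
    pi0: float
    seed: int | None = None
    mode: str = "two_class"
    _perm_d: np.ndarray | None = field(default=None, repr=False)

    def fdr_at(self, delta: float) -> tuple[float, int]:
        """(estimated FDR, called count) at an arbitrary delta.

        FDR = median permutation false-positive count x pi0 / called.  A
        zero median with a nonzero mean is below the resolution of the
        permutation set (half the permutations may sit just under the cut
        while the rest carry real exceedances), so the mean count is used
        as a continuity guard in that case.
        """
        called, cutup, cutlow = _sam_called(self.d, self.d_expected, delta, self.mode)
        n_called = int(called.sum())
        if n_called == 0:
            return 0.0, 0
        counts = ((self._perm_d >= cutup) | (self._perm_d <= cutlow)).sum(axis=1)
        fp = float(np.median(counts))
        if fp == 0.0:
            fp = float(counts.mean())
        return float(fp * self.pi0 / n_called), n_called


def _sam_rs(X: np.ndarray, codes: np.ndarray, K: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """SAM numerator r and denominator scale s per gene.

    two_class: r = mean(group1) - mean(group0); s = sqrt((1/n0+1/n1) SSW/(N-2)).
    multiclass: r = sqrt((sum 1/n_k) SSB/(K-1)); s = sqrt((sum 1/n_k) SSW/(N-K))
    — reduces to |two-class| when K = 2.
    """
    N = X.shape[1]
    n_k = np.bincount(codes, minlength=K).astype(float)
    ind = np.eye(K)[codes]
    M = (X @ ind) / n_k
    ssw = np.maximum((X**2).sum(axis=1) - (n_k * M**2).sum(axis=1), 0.0)
    inv = (1.0 / n_k).sum()
    s = np.sqrt(inv * ssw / (N - K))
    if mode == "two_class":
        if K != 2:
            raise ValueError("two_class mode requires exactly 2 labels")
        r = M[:, 1] - M[:, 0]
    else:
        grand = X.mean(axis=1)
        ssb = np.maximum((n_k * (M - grand[:, None]) ** 2).sum(axis=1), 0.0)
        r = np.sqrt(inv * ssb / (K - 1))
    return r, s


def _choose_s0(r: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """Fudge factor minimising the CV of the d spread across windows of s."""
    G = s.size
    n_windows = max(3, min(n_windows, G // 10)) if G >= 30 else 3
    qs = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    win = np.clip(np.searchsorted(qs, s, side="right") - 1, 0, n_windows - 1)
    candidates = np.quantile(s, np.arange(0, 101, 5) / 100.0)
    best_s0, best_cv = float(np.median(s)), np.inf
    for s0 in candidates:
        d = r / (s + s0 + 1e-300)
        mads = np.array([
            sps.median_abs_deviation(d[win == w], scale="normal")
            for w in range(n_windows) if (win == w).any()
        ])
        mu = mads.mean()
        if mu == 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _sam_called(d: np.ndarray, dbar: np.ndarray, delta: float, mode: str
                ) -> tuple[np.ndarray, float, float]:
    """Tusher-style asymmetric cutpoints.

    Moving away from the origin of the observed-vs-expected order-statistic
    plot, the first point whose deviation from the permutation expectation
    reaches delta sets the cut; every gene beyond it is called.
    """
    order = np.argsort(d, kind="mergesort")
    ds = d[order]
    diff = ds - dbar
    origin = int(np.searchsorted(ds, 0.0))       # first non-negative d
    up = np.nonzero(diff[origin:] >= delta)[0]
    cutup = ds[origin + up[0]] if up.size else np.inf
    if mode == "multiclass":
        cutlow = -np.inf
    else:
        down = np.nonzero(diff[:origin] <= -delta)[0]
        cutlow = ds[down[-1]] if down.size else -np.inf
    called = (d >= cutup) | (d <= cutlow)
    return called, float(cutup), float(cutlow)


def _enumerate_two_class(n: int, n1: int, max_count: int) -> list[np.ndarray] | None:
    if math.comb(n, n1) > max_count:
        return None
    out = []
    for combo in itertools.combinations(range(n), n1):
        codes = np.zeros(n, dtype=int)
        codes[list(combo)] = 1
        out.append(codes)
    return out


def _enumerate_multiclass(codes: np.ndarray, max_count: int) -> list[np.ndarray] | None:
    from sympy.utilities.iterables import multiset_permutations

    counts = np.bincount(codes)
    total = math.factorial(len(codes))
    for c in counts:
        total //= math.factorial(int(c))
    if total > max_count:
        return None
    return [np.array(p, dtype=int) for p in multiset_permutations(codes.tolist())]


def sam(
    m: ExpressionMatrix,
    labels: Sequence,
    mode: str = "two_class",
    fdr_target: float = 0.001,
    n_perms: int = 100,
    seed: int = 0,
) -> SamResult:
    """SAM with permutation-estimated FDR and automatic delta calibration.

    ``labels`` assigns every sample (column) a class.  delta is the smallest
    candidate for which estimated FDR = median permutation false positives
    x pi0 / called is at or below ``fdr_target``; the significant set is the
    genes called at that delta (possibly empty).  When ``n_perms`` is at
    least the number of distinct label assignments, all are enumerated.
    """
    if mode not in ("two_class", "multiclass"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    X = m.values
    codes, order = _encode_groups(labels)
    K = len(order)
    if K < 2:
        raise ValueError("need >= 2 classes")
    r, s = _sam_rs(X, codes, K, mode)
    s0 = _choose_s0(r, s)
    d = r / (s + s0 + 1e-300)

    # permutation null
    if mode == "two_class":
        perms = _enumerate_two_class(len(codes), int((codes == 1).sum()), n_perms)
    else:
        perms = _enumerate_multiclass(codes, n_perms)
    rng = np.random.default_rng(seed)
    if perms is None:
        perms = [rng.permutation(codes) for _ in range(n_perms)]
    B = len(perms)
    perm_d = np.empty((B, X.shape[0]))
    for b, pc in enumerate(perms):
        rb, sb = _sam_rs(X, pc, K, mode)
        perm_d[b] = rb / (sb + s0 + 1e-300)
    perm_sorted = np.sort(perm_d, axis=1)
    dbar = perm_sorted.mean(axis=0)

    # pi0 from the central 50% of the permutation d distribution
    q25, q75 = np.quantile(perm_d, [0.25, 0.75])
    pi0 = float(np.clip(((d > q25) & (d < q75)).sum() / (0.5 * d.size), 1e-3, 1.0))

    # delta grid: deviations of observed order statistics from expectation
    ds = np.sort(d)
    deltas = np.unique(np.abs(ds - dbar))
    result = SamResult(m.gene_ids, d, dbar, float(deltas[-1] + 1e-9), B, 0.0,
                       GeneSet("sam_significant", frozenset()), s0, pi0, seed, mode,
                       _perm_d=perm_d)
    chosen_called = np.zeros(d.size, dtype=bool)
    for delta in deltas:
        fdr, n_called = result.fdr_at(float(delta))
        if fdr <= fdr_target:
            called, _, _ = _sam_called(d, dbar, float(delta), mode)
            result.delta = float(delta)
            result.fdr = fdr
            chosen_called = called
            break
    result.significant = GeneSet(
        "sam_significant",
        frozenset(g for g, c in zip(m.gene_ids, chosen_called) if c),
    )
    return result
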