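"""Latent-variable models: UV-scaled PCA and OPLS-DA with permutation checks.

PCA and OPLS-DA operate on unit-variance (UV/auto-) scaled data: every
variable is centred and divided by its standard deviation, so each
contributes equally regardless of intensity.  OPLS-DA regresses the scaled
block X on a centred class-indicator Y after splitting X variation into a
class-predictive part and a class-orthogonal part (NIPALS); model size is
reported in the SIMCA-style notation predictive+orthogonal+0.  Predictive
power Q2 comes from 7-fold class-stratified cross-validation with per-fold
re-scaling; a label-permutation test quantifies overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import ExpressionMatrix

__all__ = [
    "LatentModel",
    "PermutationValidation",
    "pca_uv",
    "opls_da",
    "permutation_validation",
]

_EPS = 1e-12


@dataclass
class LatentModel:
    """Scores/loadings of a PCA or OPLS-DA fit with variance bookkeeping."""

    kind: str                                   # "pca" | "oplsda"
    scaling: str                                # "UV"
    n_predictive: int
    n_orthogonal: int
    scores: np.ndarray                          # n x A predictive scores
    loadings: np.ndarray                        # p x A predictive loadings
    r2x_per_component: np.ndarray
    r2x_cum: float
    q2: float | None = None
    r2y: float | None = None
    classes: list | None = None
    ortho_scores: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    weights: np.ndarray | None = None           # p x A predictive weights (oplsda)
    ortho_weights: np.ndarray | None = None
    y_loadings: np.ndarray | None = None        # K x A
    r2x_orthogonal: float = 0.0
    dropped_variables: list[str] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def notation(self) -> str:
        """SIMCA-style component notation, e.g. '3+2+0'."""
        return f"{self.n_predictive}+{self.n_orthogonal}+0"


@dataclass
class PermutationValidation:
    """Label-permutation overfitting check for a class model."""

    n_permutations: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: list[float]
    permuted_q2: list[float]
    p_r2y: float
    p_q2: float
    seed: int


def _uv_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, mu, sd, keep


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign each component so its largest-|loading| element is positive."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return loadings, scores


def pca_uv(m: ExpressionMatrix | np.ndarray, n_components: int,
           variable_axis: str = "genes") -> LatentModel:
    """PCA of UV-scaled data (observations = samples, variables = genes).

    Zero-variance variables are dropped with a warning.  Per-component R2X
    is the fraction of total (scaled) variance explained.
    """
    if isinstance(m, ExpressionMatrix):
        X = m.values.T if variable_axis == "genes" else m.values
        var_names = m.gene_ids if variable_axis == "genes" else m.sample_names
    else:
        X = np.asarray(m, dtype=float)
        var_names = [f"v{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 observations")
    Xs, mu, sd, keep = _uv_scale(X)
    dropped = [var_names[i] for i in np.nonzero(~keep)[0]]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance variable(s) for UV scaling")
    max_comp = min(n - 1, int(keep.sum()))
    if n_components > max_comp:
        raise ValueError(f"n_components {n_components} exceeds min(obs-1, variables) = {max_comp}")
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    total_ss = float((Xs**2).sum())
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    loadings, scores = _fix_signs(loadings, scores)
    r2x = (S[:n_components] ** 2) / total_ss
    return LatentModel(
        kind="pca", scaling="UV", n_predictive=n_components, n_orthogonal=0,
        scores=scores, loadings=loadings, r2x_per_component=r2x,
        r2x_cum=float(r2x.sum()), dropped_variables=dropped,
        center=mu, scale=sd,
    )


# ---------------------------------------------------------------------------
# OPLS-DA


def _class_indicator(classes: Sequence) -> tuple[np.ndarray, list]:
    order: dict = {}
    for c in classes:
        order.setdefault(c, len(order))
    Y = np.zeros((len(classes), len(order)))
    for i, c in enumerate(classes):
        Y[i, order[c]] = 1.0
    return Y, list(order)


def _nipals_pls_component(X: np.ndarray, Y: np.ndarray,
                          max_iter: int = 500, tol: float = 1e-10
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One PLS2 component: weights w, scores t, X-loadings p, Y-loadings c."""
    u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
    w = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w_new = X.T @ u
        nrm = np.linalg.norm(w_new)
        if nrm < _EPS:
            break
        w_new /= nrm
        t = X @ w_new
        c = Y.T @ t / max(t @ t, _EPS)
        u_new = Y @ c / max(c @ c, _EPS)
        if np.linalg.norm(w_new - w) < tol:
            w, u = w_new, u_new
            break
        w, u = w_new, u_new
    t = X @ w
    p = X.T @ t / max(t @ t, _EPS)
    c = Y.T @ t / max(t @ t, _EPS)
    return w, t, p, c


def _fit_opls(Xs: np.ndarray, Yc: np.ndarray, n_pred: int, n_orth: int) -> dict:
    """Core OPLS fit on pre-scaled X and centred Y; returns parameter dict."""
    total_ss = float((Xs**2).sum())
    Xd = Xs.copy()
    # orthonormal basis of the Y-correlated subspace span(X'Y)
    Wy = np.linalg.qr(Xd.T @ Yc)[0] if n_orth else None
    w_o_list, p_o_list, t_o_list = [], [], []
    r2x_orth = []
    for _ in range(n_orth):
        _, _, p_load, _ = _nipals_pls_component(Xd, Yc)
        w_o = p_load - Wy @ (Wy.T @ p_load)
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-10:
            break
        w_o /= nrm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / max(t_o @ t_o, _EPS)
        Xd = Xd - np.outer(t_o, p_o)
        w_o_list.append(w_o)
        p_o_list.append(p_o)
        t_o_list.append(t_o)
        r2x_orth.append(float((t_o @ t_o) * (p_o @ p_o)) / total_ss)
    Xp = Xd
    Yd = Yc.copy()
    W, T, P, C = [], [], [], []
    r2x_pred = []
    for _ in range(n_pred):
        w, t, p, c = _nipals_pls_component(Xp, Yd)
        if np.linalg.norm(t) < 1e-10:
            break
        W.append(w)
        T.append(t)
        P.append(p)
        C.append(c)
        r2x_pred.append(float((t @ t) * (p @ p)) / total_ss)
        Xp = Xp - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
    r2y = 1.0 - float((Yd**2).sum()) / max(float((Yc**2).sum()), _EPS)
    return {
        "w_o": np.array(w_o_list).T if w_o_list else np.zeros((Xs.shape[1], 0)),
        "p_o": np.array(p_o_list).T if p_o_list else np.zeros((Xs.shape[1], 0)),
        "t_o": np.array(t_o_list).T if t_o_list else np.zeros((Xs.shape[0], 0)),
        "W": np.array(W).T, "T": np.array(T).T, "P": np.array(P).T, "C": np.array(C).T,
        "r2x_pred": np.array(r2x_pred), "r2x_orth": np.array(r2x_orth), "r2y": r2y,
    }


def _opls_predict(fit: dict, Xs: np.ndarray) -> np.ndarray:
    """Predict centred-Y for pre-scaled rows using a fitted parameter dict."""
    Xd = Xs.copy()
    for a in range(fit["w_o"].shape[1]):
        t_o = Xd @ fit["w_o"][:, a]
        Xd = Xd - np.outer(t_o, fit["p_o"][:, a])
    Yhat = np.zeros((Xs.shape[0], fit["C"].shape[0]))
    for a in range(fit["W"].shape[1]):
        t = Xd @ fit["W"][:, a]
        Yhat += np.outer(t, fit["C"][:, a])
        Xd = Xd - np.outer(t, fit["P"][:, a])
    return Yhat


def _stratified_folds(codes: np.ndarray, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic class-stratified fold assignment (round-robin per class)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(codes.size, dtype=int)
    for k in np.unique(codes):
        idx = np.nonzero(codes == k)[0]
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return [np.nonzero(fold == f)[0] for f in range(n_folds)]


def _cross_validated_q2(X: np.ndarray, Y: np.ndarray, codes: np.ndarray,
                        n_pred: int, n_orth: int, n_folds: int = 7,
                        seed: int = 0) -> float:
    """Q2 = 1 - PRESS/TSS over class-stratified folds, per-fold UV re-scaling."""
    n_folds = min(n_folds, min(np.bincount(codes)) * 2, X.shape[0] - 1)
    n_folds = max(n_folds, 2)
    folds = _stratified_folds(codes, n_folds, seed)
    press = 0.0
    tss = 0.0
    for test_idx in folds:
        if test_idx.size == 0:
            continue
        train = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        Xtr, mu, sd, keep = _uv_scale(X[train])
        ymean = Y[train].mean(axis=0)
        Ytr = Y[train] - ymean
        fit = _fit_opls(Xtr, Ytr, n_pred, n_orth)
        Xte = (X[test_idx][:, keep] - mu[keep]) / sd[keep]
        Yte = Y[test_idx] - ymean
        press += float(((Yte - _opls_predict(fit, Xte)) ** 2).sum())
        tss += float((Yte**2).sum())
    return 1.0 - press / max(tss, _EPS)


def opls_da(
    m: ExpressionMatrix | np.ndarray,
    classes: Sequence,
    n_predictive: int,
    n_orthogonal: int = 0,
    n_folds: int = 7,
    cv_seed: int = 0,
) -> LatentModel:
    """OPLS-DA of UV-scaled X against a centred class-indicator Y.

    Class-orthogonal X variation is stripped component by component before
    the predictive PLS fit; R2X is split into predictive and orthogonal
    parts and Q2 comes from ``n_folds``-fold stratified cross-validation.
    Observations are samples (columns of an :class:`ExpressionMatrix`).
    """
    if isinstance(m, ExpressionMatrix):
        X = m.values.T
    else:
        X = np.asarray(m, dtype=float)
    Y, class_order = _class_indicator(classes)
    if len(class_order) < 2:
        raise ValueError("need >= 2 classes")
    counts = Y.sum(axis=0)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 observations")
    Xs, mu, sd, keep = _uv_scale(X)
    rank = np.linalg.matrix_rank(Xs)
    if n_predictive + n_orthogonal >= rank:
        raise ValueError(
            f"n_predictive + n_orthogonal = {n_predictive + n_orthogonal} must be < rank(X) = {rank}"
        )
    codes = np.argmax(Y, axis=1)
    Yc = Y - Y.mean(axis=0)
    fit = _fit_opls(Xs, Yc, n_predictive, n_orthogonal)
    q2 = _cross_validated_q2(X, Y, codes, n_predictive, n_orthogonal,
                             n_folds=n_folds, seed=cv_seed)
    loadings, scores = _fix_signs(fit["P"].copy(), fit["T"].copy())
    return LatentModel(
        kind="oplsda", scaling="UV",
        n_predictive=fit["W"].shape[1], n_orthogonal=fit["w_o"].shape[1],
        scores=scores, loadings=loadings,
        r2x_per_component=fit["r2x_pred"],
        r2x_cum=float(fit["r2x_pred"].sum() + fit["r2x_orth"].sum()),
        r2x_orthogonal=float(fit["r2x_orth"].sum()),
        q2=q2, r2y=fit["r2y"], classes=list(class_order),
        ortho_scores=fit["t_o"], ortho_loadings=fit["p_o"],
        weights=fit["W"], ortho_weights=fit["w_o"], y_loadings=fit["C"],
        center=mu, scale=sd,
    )


def permutation_validation(
    m: ExpressionMatrix | np.ndarray,
    classes: Sequence,
    n_predictive: int,
    n_orthogonal: int = 0,
    n_perms: int = 100,
    seed: int = 0,
) -> PermutationValidation:
    """Refit the class model under permuted labels to gauge overfitting.

    Empirical p = (1 + #{permuted Q2 >= observed Q2}) / (n_perms + 1);
    analogously for R2Y.  Deterministic for a fixed seed.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    classes = list(classes)
    obs = opls_da(m, classes, n_predictive, n_orthogonal, cv_seed=seed)
    rng = np.random.default_rng(seed)
    perm_r2, perm_q2 = [], []
    for _ in range(n_perms):
        perm = [classes[i] for i in rng.permutation(len(classes))]
        try:
            pm = opls_da(m, perm, n_predictive, n_orthogonal, cv_seed=seed)
            perm_r2.append(pm.r2y)
            perm_q2.append(pm.q2)
        except ValueError:
            # a permutation can starve a class below 2 members only if the
            # design is tiny; count it as a tie against the observed model
            perm_r2.append(obs.r2y)
            perm_q2.append(obs.q2)
    p_q2 = (1 + sum(q >= obs.q2 for q in perm_q2)) / (n_perms + 1)
    p_r2 = (1 + sum(r >= obs.r2y for r in perm_r2)) / (n_perms + 1)
    return PermutationValidation(
        n_permutations=n_perms,
        observed_r2y=obs.r2y, observed_q2=obs.q2,
        permuted_r2y=perm_r2, permuted_q2=perm_q2,
        p_r2y=p_r2, p_q2=p_q2, seed=seed,
    )
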