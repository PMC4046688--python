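"""Maximum-likelihood animal-model engine and likelihood-ratio testing.

Single-trait models  y = Xb + u + e,  u ~ N(0, A s2u),  e ~ N(0, I s2e)
are fitted through a one-time spectral decomposition of the phenotyped
submatrix of A: in the eigenbasis the covariance is diagonal for any
variance ratio lam = s2u/s2e, fixed effects and s2e are profiled out in
closed form, and the fit reduces to a one-dimensional search over lam.

Multi-trait models use the same transform: with complete records the
covariance A (x) G0 + I (x) R0 becomes block diagonal with k x k blocks
d_i G0 + R0, and the fit is a quasi-Newton optimization over the matrix
square roots (log-Cholesky factors) of G0 and R0 with fixed effects
profiled by GLS.  Records missing one trait of a pair fall back to a
dense marginal-likelihood path over the observed entries.

Estimation is full maximum likelihood (not REML) throughout so that
likelihood-ratio tests across fixed-effect structures (QTL and SNP
effects) are valid; p-values come from the chi-square distribution with
df equal to the difference in the number of estimated parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import Dataset
from .pedkin import RelationshipMatrix

_LOG2PI = np.log(2.0 * np.pi)
_PHI_LO, _PHI_HI = -18.0, 12.0  # bounds for log variance ratio


class SingularDesignError(ValueError):
    pass


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise SingularDesignError(f"design is rank deficient; collinear columns: {bad}")


def build_fixed_design(
    phen: pd.DataFrame, covariates: Sequence[str] = ("sex", "batch", "carcass_wt")
) -> Tuple[np.ndarray, List[str]]:
    """Reference-coded fixed design: intercept, sex, batch dummies, slope."""
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    if "sex" in covariates:
        cols.append((phen["sex"] == "M").to_numpy(float))
        names.append("sex[M]")
    if "batch" in covariates:
        levels = sorted(phen["batch"].unique())
        for lev in levels[1:]:
            cols.append((phen["batch"] == lev).to_numpy(float))
            names.append(f"batch[{lev}]")
    if "carcass_wt" in covariates:
        cols.append(phen["carcass_wt"].to_numpy(float))
        names.append("carcass_wt")
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


@dataclass
class ModelSpec:
    """Declarative model: traits, nuisance covariates, genetic columns.

    ``genetic_columns`` maps a label to either a single coefficient
    vector (one shared-effect column added to every trait's design, with
    a separate effect per trait) or a dict {trait: vector} restricting
    the column to particular traits.
    """

    traits: Tuple[str, ...]
    covariates: Tuple[str, ...] = ("sex", "batch", "carcass_wt")
    genetic_columns: Dict[str, object] = field(default_factory=dict)


@dataclass
class FitResult:
    loglik: float
    beta: pd.Series
    se: pd.Series
    varcomp: dict
    converged: bool
    n: int
    n_params: int

    def effect(self, label: str) -> Tuple[float, float]:
        return float(self.beta[label]), float(self.se[label])


@dataclass
class LRTest:
    lr: float
    df: int
    p: float


class SpectralBasis:
    """Eigendecomposition of a phenotyped submatrix of A, cached per cohort."""

    def __init__(self, A_sub: np.ndarray, ids: Sequence):
        self.ids = list(ids)
        d, U = np.linalg.eigh(A_sub)
        self.d = np.clip(d, 0.0, None)
        self.U = U

    @classmethod
    def from_relationship(cls, A: RelationshipMatrix, ids: Sequence) -> "SpectralBasis":
        return cls(A.submatrix(list(ids)).matrix, ids)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M


# ---------------------------------------------------------------------------
# single trait

def _profile_single(lam: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profiled log-likelihood at variance ratio lam; returns
    (loglik, beta, sigma2_e, XtWX)."""
    n = len(yt)
    c = lam * d + 1.0
    w = 1.0 / c
    XtW = Xt * w[:, None]
    XtWX = XtW.T @ Xt
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.dot(w * r, r))
    sigma2 = rss / n
    ll = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + n + float(np.sum(np.log(c))))
    return ll, beta, sigma2, XtWX


def fit_single_trait(
    y: np.ndarray,
    X: np.ndarray,
    basis: SpectralBasis,
    names: Optional[Sequence[str]] = None,
    fix_ratio: Optional[float] = None,
    tol: float = 1e-9,
) -> FitResult:
    """ML fit of the single-trait animal model via the spectral fast path."""
    y = np.asarray(y, float)
    names = list(names) if names is not None else [f"b{i}" for i in range(X.shape[1])]
    _check_full_rank(X, names)
    yt = basis.U.T @ y
    Xt = basis.U.T @ X
    d = basis.d
    n = len(y)

    if fix_ratio is not None:
        lam = float(fix_ratio)
        converged = True
    else:
        neg = lambda phi: -_profile_single(np.exp(phi), yt, Xt, d)[0]
        res = optimize.minimize_scalar(
            neg, bounds=(_PHI_LO, _PHI_HI), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        # compare against the no-polygenic boundary
        if _profile_single(0.0, yt, Xt, d)[0] >= -res.fun - tol:
            lam = 0.0
        converged = bool(res.success)

    ll, beta, sigma2, XtWX = _profile_single(lam, yt, Xt, d)
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        loglik=ll,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        varcomp={
            "sigma2_u": lam * sigma2,
            "sigma2_e": sigma2,
            "h2": lam / (1.0 + lam),
        },
        converged=converged,
        n=n,
        n_params=X.shape[1] + 2,
    )


def _profile_single_vec(phis, Yt, Xt, d):
    """Vectorized profiled log-likelihood: one ratio per response column.

    Yt: (n, m) rotated responses; phis: (m,).  Returns (ll (m,), beta
    (m, p), sigma2 (m,), XtWX (m, p, p))."""
    n, m = Yt.shape
    lam = np.exp(phis)
    C = lam[None, :] * d[:, None] + 1.0  # (n, m)
    W = 1.0 / C
    XtWX = np.einsum("nm,np,nq->mpq", W, Xt, Xt, optimize=True)
    XtWy = np.einsum("np,nm->mp", Xt, W * Yt, optimize=True)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    resid = Yt - Xt @ beta.T  # (n, m)
    rss = np.einsum("nm,nm->m", W * resid, resid)
    sigma2 = rss / n
    ll = -0.5 * (
        n * _LOG2PI + n * np.log(sigma2) + n + np.sum(np.log(C), axis=0)
    )
    return ll, beta, sigma2, XtWX


def fit_single_trait_many(
    Y: np.ndarray,
    X: np.ndarray,
    basis: SpectralBasis,
    iters: int = 40,
) -> dict:
    """Vectorized ML fits of many responses sharing one design.

    Golden-section search on log variance ratio, carried independently
    per response but evaluated in lock-step; used by the scan stages
    where hundreds of probes share the design at each tested position.
    Returns arrays: loglik, beta (m, p), se_last, sigma2_u, sigma2_e.
    """
    Yt = basis.U.T @ np.asarray(Y, float)
    Xt = basis.U.T @ X
    d = basis.d
    m = Yt.shape[1]
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(m, _PHI_LO)
    b = np.full(m, _PHI_HI)
    x1 = b - gr * (b - a)
    x2 = a + gr * (b - a)
    f1 = _profile_single_vec(x1, Yt, Xt, d)[0]
    f2 = _profile_single_vec(x2, Yt, Xt, d)[0]
    for _ in range(iters):
        take1 = f1 >= f2  # maximum lies in [a, x2]
        b = np.where(take1, x2, b)
        a = np.where(take1, a, x1)
        x1n = b - gr * (b - a)
        x2n = a + gr * (b - a)
        # the surviving interior point is reused; only one new evaluation
        f_new = _profile_single_vec(np.where(take1, x1n, x2n), Yt, Xt, d)[0]
        x1, x2, f1, f2 = (
            np.where(take1, x1n, x2),
            np.where(take1, x1, x2n),
            np.where(take1, f_new, f2),
            np.where(take1, f1, f_new),
        )
    phi = np.where(f1 >= f2, x1, x2)
    ll, beta, sigma2, XtWX = _profile_single_vec(phi, Yt, Xt, d)
    # boundary comparison at lam ~ 0
    ll0, beta0, sigma20, XtWX0 = _profile_single_vec(np.full(m, -300.0), Yt, Xt, d)
    at0 = ll0 >= ll
    ll = np.where(at0, ll0, ll)
    beta = np.where(at0[:, None], beta0, beta)
    sigma2 = np.where(at0, sigma20, sigma2)
    XtWX = np.where(at0[:, None, None], XtWX0, XtWX)
    lam = np.where(at0, 0.0, np.exp(phi))
    cov = np.linalg.inv(XtWX) * sigma2[:, None, None]
    se = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    return {
        "loglik": ll,
        "beta": beta,
        "se": se,
        "sigma2_u": lam * sigma2,
        "sigma2_e": sigma2,
    }


# ---------------------------------------------------------------------------
# multi trait

def _chol_from_theta(theta: np.ndarray, k: int) -> np.ndarray:
    """Lower-triangular factor from a log-Cholesky parameter vector."""
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


def _theta_from_cov(M: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    k = M.shape[0]
    w, V = np.linalg.eigh(M)
    M = (V * np.clip(w, floor, None)) @ V.T
    L = np.linalg.cholesky(M)
    out = []
    for i in range(k):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.asarray(out)


def _mt_profile_2(G0, R0, Yt, Xts, d):
    """Closed-form bivariate specialization of :func:`_mt_profile`."""
    n = Yt.shape[0]
    a = d * G0[0, 0] + R0[0, 0]
    b = d * G0[0, 1] + R0[0, 1]
    c = d * G0[1, 1] + R0[1, 1]
    det = a * c - b * b
    if (det <= 0).any() or (a <= 0).any():
        return -np.inf, None, None, None
    w11, w12, w22 = c / det, -b / det, a / det
    X1, X2 = Xts
    p1, p2 = X1.shape[1], X2.shape[1]
    M = np.empty((p1 + p2, p1 + p2))
    M[:p1, :p1] = (X1 * w11[:, None]).T @ X1
    M[:p1, p1:] = (X1 * w12[:, None]).T @ X2
    M[p1:, :p1] = M[:p1, p1:].T
    M[p1:, p1:] = (X2 * w22[:, None]).T @ X2
    y1, y2 = Yt[:, 0], Yt[:, 1]
    rhs = np.concatenate([
        X1.T @ (w11 * y1 + w12 * y2),
        X2.T @ (w12 * y1 + w22 * y2),
    ])
    try:
        beta = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    r1 = y1 - X1 @ beta[:p1]
    r2 = y2 - X2 @ beta[p1:]
    quad = float(np.dot(w11 * r1, r1) + 2.0 * np.dot(w12 * r1, r2) + np.dot(w22 * r2, r2))
    ll = -0.5 * (2 * n * _LOG2PI + float(np.sum(np.log(det))) + quad)
    return ll, beta, M, quad


def _mt_profile(
    G0: np.ndarray, R0: np.ndarray, Yt: np.ndarray, Xts: Sequence[np.ndarray],
    d: np.ndarray,
):
    """Profiled multi-trait log-likelihood with complete records.

    Yt: (n, k) rotated responses; Xts: per-trait rotated designs.
    Block covariance per (rotated) individual: d_i G0 + R0."""
    n, k = Yt.shape
    if k == 2:
        return _mt_profile_2(G0, R0, Yt, Xts, d)
    Sig = d[:, None, None] * G0[None] + R0[None]  # (n, k, k)
    sign, logdet = np.linalg.slogdet(Sig)
    if (sign <= 0).any():
        return -np.inf, None, None, None
    Sinv = np.linalg.inv(Sig)
    ps = [x.shape[1] for x in Xts]
    P = sum(ps)
    M = np.empty((P, P))
    rhs = np.empty(P)
    off = np.cumsum([0] + ps)
    for t in range(k):
        for s in range(k):
            blk = np.einsum("n,np,nq->pq", Sinv[:, t, s], Xts[t], Xts[s], optimize=True)
            M[off[t]:off[t + 1], off[s]:off[s + 1]] = blk
        rhs[off[t]:off[t + 1]] = np.einsum(
            "np,n->p", Xts[t], np.einsum("ns,ns->n", Sinv[:, t, :], Yt), optimize=True
        )
    try:
        beta = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    R = Yt - np.column_stack(
        [Xts[t] @ beta[off[t]:off[t + 1]] for t in range(k)]
    )
    quad = float(np.einsum("nt,nts,ns->", R, Sinv, R, optimize=True))
    ll = -0.5 * (n * k * _LOG2PI + float(logdet.sum()) + quad)
    return ll, beta, M, quad


def _mt_dense_loglik(
    G0: np.ndarray, R0: np.ndarray, Y: np.ndarray, Xs: Sequence[np.ndarray],
    A_sub: np.ndarray,
):
    """Dense marginal likelihood over the observed (individual, trait)
    entries; used when one trait of a pair is missing for some animals."""
    n, k = Y.shape
    obs = ~np.isnan(Y)
    sel = obs.reshape(-1)
    V = (np.kron(A_sub, G0) + np.kron(np.eye(n), R0))[np.ix_(sel, sel)]
    ps = [x.shape[1] for x in Xs]
    Xbig = np.zeros((n * k, sum(ps)))
    off = np.cumsum([0] + ps)
    for t in range(k):
        Xbig[t::k, off[t]:off[t + 1]] = Xs[t]
    Xo = Xbig[sel]
    yo = Y.reshape(-1)[sel]
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    Vi_X = np.linalg.solve(V, Xo)
    M = Xo.T @ Vi_X
    beta = np.linalg.solve(M, Vi_X.T @ yo)
    r = yo - Xo @ beta
    alpha = np.linalg.solve(c, r)
    quad = float(alpha @ alpha)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    ll = -0.5 * (len(yo) * _LOG2PI + logdet + quad)
    return ll, beta, M


def fit_multitrait(
    Y: np.ndarray,
    Xs: Sequence[np.ndarray],
    basis: SpectralBasis,
    names: Optional[Sequence[str]] = None,
    x0: Optional[np.ndarray] = None,
    fix_varcomp: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    tol: float = 1e-8,
) -> FitResult:
    """ML fit of a k-trait animal model with per-trait fixed designs.

    With complete records the spectral fast path is used; otherwise a
    dense marginal-likelihood path over observed entries.  ``x0`` warm
    starts the (log-Cholesky G0, log-Cholesky R0) parameter vector;
    ``fix_varcomp=(G0, R0)`` skips the optimization (fast mode for grid
    profiling) and only profiles the fixed effects.
    """
    Y = np.asarray(Y, float)
    n, k = Y.shape
    ps = [x.shape[1] for x in Xs]
    if names is None:
        names = [f"t{t}:b{i}" for t in range(k) for i in range(ps[t])]
    complete = not np.isnan(Y).any()
    npar_cov = k * (k + 1)  # two log-Cholesky factors

    if complete:
        Yt = basis.U.T @ Y
        Xts = [basis.U.T @ x for x in Xs]
        d = basis.d

        def eval_ll(G0, R0):
            return _mt_profile(G0, R0, Yt, Xts, d)
    else:
        A_sub = basis.U @ np.diag(basis.d) @ basis.U.T

        def eval_ll(G0, R0):
            ll, beta, M = _mt_dense_loglik(G0, R0, Y, Xs, A_sub)
            return ll, beta, M, None

    if fix_varcomp is not None:
        G0, R0 = fix_varcomp
        ll, beta, M, _ = eval_ll(np.asarray(G0, float), np.asarray(R0, float))
        se = np.sqrt(np.diag(np.linalg.inv(M)))
        return FitResult(
            loglik=ll, beta=pd.Series(beta, index=names),
            se=pd.Series(se, index=names),
            varcomp={"G0": np.asarray(G0, float), "R0": np.asarray(R0, float)},
            converged=True, n=n, n_params=sum(ps),
        )

    if x0 is None:
        x0 = _default_mt_start(Y, Xs, basis, k)

    nt = k * (k + 1) // 2
    diag_idx = np.cumsum(np.arange(1, k + 1)) - 1

    def neg(theta):
        Lg = _chol_from_theta(theta[:nt], k)
        Lr = _chol_from_theta(theta[nt:], k)
        ll = eval_ll(Lg @ Lg.T, Lr @ Lr.T)[0]
        return -ll if np.isfinite(ll) else 1e12

    bounds = []
    for half in range(2):
        for idx in range(nt):
            if idx in diag_idx:
                bounds.append((-8.0, 5.0))
            else:
                bounds.append((-30.0, 30.0))
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": tol, "gtol": 1e-7, "maxiter": 300},
    )
    theta = res.x
    Lg = _chol_from_theta(theta[:nt], k)
    Lr = _chol_from_theta(theta[nt:], k)
    G0, R0 = Lg @ Lg.T, Lr @ Lr.T
    ll, beta, M, _ = eval_ll(G0, R0)
    se = np.sqrt(np.diag(np.linalg.inv(M)))
    fit = FitResult(
        loglik=ll, beta=pd.Series(beta, index=names), se=pd.Series(se, index=names),
        varcomp={"G0": G0, "R0": R0, "theta": theta},
        converged=bool(res.success), n=n, n_params=sum(ps) + npar_cov,
    )
    if not res.success:
        warnings.warn("multi-trait fit did not converge; result flagged")
    return fit


def _default_mt_start(Y, Xs, basis, k) -> np.ndarray:
    """Method-of-moments start: per-trait single fits for the variance
    split, OLS residual correlations for the off-diagonals."""
    g_diag, r_diag, resids = [], [], []
    for t in range(k):
        y = Y[:, t]
        ok = ~np.isnan(y)
        if ok.all():
            f = fit_single_trait(y, Xs[t], basis)
            g_diag.append(max(f.varcomp["sigma2_u"], 1e-4))
            r_diag.append(max(f.varcomp["sigma2_e"], 1e-4))
        else:
            v = np.nanvar(y)
            g_diag.append(0.3 * v + 1e-4)
            r_diag.append(0.7 * v + 1e-4)
        b, *_ = np.linalg.lstsq(Xs[t][ok], y[ok], rcond=None)
        r = np.full(len(y), np.nan)
        r[ok] = y[ok] - Xs[t][ok] @ b
        resids.append(r)
    Rmat = pd.DataFrame(np.column_stack(resids)).corr().to_numpy()
    Rmat = np.nan_to_num(Rmat, nan=0.0)
    np.fill_diagonal(Rmat, 1.0)
    half = 0.5 * Rmat
    np.fill_diagonal(half, 1.0)
    G0 = np.sqrt(np.outer(g_diag, g_diag)) * half
    R0 = np.sqrt(np.outer(r_diag, r_diag)) * half
    return np.concatenate([_theta_from_cov(G0), _theta_from_cov(R0)])


# ---------------------------------------------------------------------------
# tests

def chisq_pvalue(lr: float, df: int) -> float:
    """Upper-tail chi-square probability of an LR statistic."""
    if lr < 0:
        raise ValueError("LR statistic must be nonnegative")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(lr, df))


def lr_test(full: FitResult, reduced: FitResult, df: int) -> LRTest:
    """2 * (loglik_full - loglik_reduced) against chi-square(df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    lr = 2.0 * (full.loglik - reduced.loglik)
    if lr < -1e-6:
        warnings.warn(
            f"negative LR statistic {lr:.3g}: optimizer failure in the nested pair"
        )
    lr = max(lr, 0.0)
    return LRTest(lr=lr, df=df, p=chisq_pvalue(lr, df))


# ---------------------------------------------------------------------------
# spec-level wrapper

def fit_model(
    dataset: Dataset,
    spec: ModelSpec,
    A: RelationshipMatrix,
    basis: Optional[SpectralBasis] = None,
    **kwargs,
) -> FitResult:
    """Assemble designs from a Dataset and dispatch on trait count."""
    phen = dataset.phenotypes.table
    traits = list(spec.traits)
    obs_any = phen[traits].notna().any(axis=1)
    phen = phen[obs_any].reset_index(drop=True)
    ids = list(phen["id"])
    if basis is None:
        basis = SpectralBasis.from_relationship(A, ids)
    F, fnames = build_fixed_design(phen, spec.covariates)

    def genetic_for(trait):
        cols, labels = [], []
        for label, vec in spec.genetic_columns.items():
            if isinstance(vec, dict):
                if trait in vec:
                    cols.append(np.asarray(vec[trait], float))
                    labels.append(label)
            else:
                cols.append(np.asarray(vec, float))
                labels.append(label)
        return cols, labels

    if len(traits) == 1:
        y = phen[traits[0]].to_numpy(float)
        cols, labels = genetic_for(traits[0])
        X = np.column_stack([F] + cols) if cols else F
        return fit_single_trait(y, X, basis, names=fnames + labels, **kwargs)

    Y = phen[traits].to_numpy(float)
    Xs, names = [], []
    for trait in traits:
        cols, labels = genetic_for(trait)
        X = np.column_stack([F] + cols) if cols else F
        Xs.append(X)
        names.extend([f"{trait}:{nm}" for nm in fnames + labels])
    return fit_multitrait(Y, Xs, basis, names=names, **kwargs)
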