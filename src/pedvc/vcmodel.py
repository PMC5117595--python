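"""Pedigree mixed-effects variance-components models.

The phenotype vector is modelled as

    y = X beta + g + e,    g ~ N(0, A * V_A),    e ~ N(0, I * V_E)

where ``A`` is the additive relationship matrix, so relatives covary in
proportion to their relationship.  Heritability is ``h2 = V_A/(V_A+V_E)``.
For ``T`` traits the genetic effects have covariance ``A (x) G`` and the
residuals ``I (x) E`` (Kronecker products over the individuals-by-traits
layout), with genetic/environmental correlations read off ``G`` and ``E``.

Estimation is REML by default (ML available).  The univariate fit profiles
the total variance and optimises the heritability ratio on [0, 1] by a
deterministic grid-plus-Brent search; the multivariate fit optimises
Cholesky factors of ``G`` and ``E`` (PSD by construction) by quasi-Newton.
Both reduce the likelihood to O(n) per evaluation through the cached
eigendecomposition of ``A``; a dense observed-block likelihood handles
per-individual missing traits and doubles as the direct oracle that the
fast path is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .kinship import RelationshipMatrix, align_to_samples
from .pedio import PhenotypeTable

__all__ = [
    "UnivariateVarianceComponents",
    "MultivariateVarianceComponents",
    "fit_univariate",
    "fit_multivariate",
    "loglik_direct",
    "lrt_heritability",
    "wald_fixed_effects",
]

_LOG2PI = np.log(2.0 * np.pi)


class ModelDataError(ValueError):
    """Data do not support the requested model."""


# ---------------------------------------------------------------------------
# design construction


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, PhenotypeTable):
        return data.data
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError("data must be a PhenotypeTable or DataFrame")


def _numeric_column(df: pd.DataFrame, name: str) -> pd.Series:
    if name not in df.columns:
        raise ModelDataError(f"column {name!r} not in phenotype table")
    col = df[name]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        if set(col.dropna().unique()) <= {"male", "female"}:
            col = col.map({"male": 1.0, "female": 0.0})
        else:
            raise ModelDataError(f"column {name!r} is not numeric")
    return pd.to_numeric(col, errors="coerce")


def _build_design(
    data,
    traits: list[str],
    fixed_effects: list[str],
    require_complete_traits: bool,
    min_rows: int = 2,
):
    """Assemble trait matrix Y, design X and the ids actually used.

    Rows need complete covariates; trait completeness is required only when
    ``require_complete_traits`` (univariate / fast multivariate path).
    """
    df = _as_frame(data)
    if len(set(traits)) != len(traits):
        raise ModelDataError(f"duplicated trait name in {traits}")
    Y = pd.concat([_numeric_column(df, t) for t in traits], axis=1)
    Y.columns = traits
    terms = ["(intercept)"] + list(fixed_effects)
    X = pd.DataFrame({"(intercept)": np.ones(len(df))}, index=df.index)
    for term in fixed_effects:
        X[term] = _numeric_column(df, term)
    keep = X.notna().all(axis=1)
    if require_complete_traits:
        keep &= Y.notna().all(axis=1)
    else:
        keep &= Y.notna().any(axis=1)
    ids = list(df.index[keep].astype(str))
    if len(ids) < min_rows:
        raise ModelDataError(f"fewer than {min_rows} complete rows")
    Xm = X.loc[keep].to_numpy(float)
    Ym = Y.loc[keep].to_numpy(float)
    # collinearity check with named offenders
    _, R, piv = scipy.linalg.qr(Xm, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xm.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < Xm.shape[1]:
        bad = [terms[k] for k in piv[rank:]]
        raise ModelDataError(f"singular fixed-effect design; collinear terms: {bad}")
    return Ym, Xm, ids, terms


def _aligned(relationship: RelationshipMatrix, ids: list[str]) -> RelationshipMatrix:
    if relationship.ids == ids:
        return relationship
    return align_to_samples(relationship, ids)


# ---------------------------------------------------------------------------
# univariate REML/ML in the eigenbasis of A


def _uni_loglik_rotated(yr, Xr, d, va, ve, method):
    """Profile (over beta) log-likelihood at variance components (va, ve)."""
    w = va * d + ve
    if np.any(w <= 0):
        raise ValueError("non-positive-definite covariance (V_A, V_E)")
    n, p = Xr.shape
    Wi = 1.0 / w
    XtWX = Xr.T @ (Xr * Wi[:, None])
    XtWy = Xr.T @ (yr * Wi)
    cf = scipy.linalg.cho_factor(XtWX)
    beta = scipy.linalg.cho_solve(cf, XtWy)
    r = yr - Xr @ beta
    quad = float(r @ (r * Wi))
    logdetV = float(np.sum(np.log(w)))
    if method == "reml":
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetC + quad)
    else:
        ll = -0.5 * (n * _LOG2PI + logdetV + quad)
    return ll, beta, XtWX


def _uni_profile_gamma(yr, Xr, d, gamma, method):
    """Profile out both beta and the total variance at heritability gamma."""
    n, p = Xr.shape
    dof = n - p if method == "reml" else n
    w = gamma * d + (1.0 - gamma)
    if np.any(w <= 1e-300):
        return -np.inf, np.nan
    Wi = 1.0 / w
    XtWX = Xr.T @ (Xr * Wi[:, None])
    XtWy = Xr.T @ (yr * Wi)
    cf = scipy.linalg.cho_factor(XtWX)
    beta = scipy.linalg.cho_solve(cf, XtWy)
    r = yr - Xr @ beta
    quad = float(r @ (r * Wi))
    s2 = quad / dof
    if s2 <= 0:
        return -np.inf, np.nan
    logdetW = float(np.sum(np.log(w)))
    if method == "reml":
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (dof * (_LOG2PI + np.log(s2) + 1.0) + logdetW + logdetC)
    else:
        ll = -0.5 * (dof * (_LOG2PI + np.log(s2) + 1.0) + logdetW)
    return ll, s2


class UnivariateVarianceComponents(BaseEstimator):
    """Additive-genetic + residual variance decomposition for one trait.

    Parameters
    ----------
    trait:
        Phenotype column to decompose (analysed on whatever scale it is
        supplied on; transform upstream).
    fixed_effects:
        Covariate columns; an intercept is always included.
    method:
        ``"reml"`` (default) or ``"ml"``.
    va_zero:
        Fit the null model with V_A constrained to 0 (for likelihood-ratio
        tests of heritability).

    Attributes (after ``fit``)
    --------------------------
    VA_, VE_, h2_ : point estimates; ``h2_ = VA_/(VA_+VE_)``.
    h2_se_, VA_se_, VE_se_ : delta-method / observed-information SEs.
    beta_, beta_se_ : fixed effects and their asymptotic SEs.
    loglik_ : restricted (or full) log-likelihood at the optimum.
    boundary_ : True when the V_A estimate sits on the 0 (or 1) boundary.
    identifiable_ : False when A is proportional to I (founders only), in
        which case h2 is not identified and only the total variance is.
    n_used_, ids_used_ : complete-case rows entering the fit.
    """

    def __init__(
        self,
        trait: str = "y",
        fixed_effects: tuple = (),
        method: str = "reml",
        va_zero: bool = False,
        grid_size: int = 101,
        tol: float = 1e-10,
    ):
        self.trait = trait
        self.fixed_effects = fixed_effects
        self.method = method
        self.va_zero = va_zero
        self.grid_size = grid_size
        self.tol = tol

    def fit(self, data, relationship: RelationshipMatrix):
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        Y, X, ids, terms = _build_design(
            data, [self.trait], list(self.fixed_effects), True
        )
        y = Y[:, 0]
        if np.var(y) == 0:
            raise ModelDataError(f"zero phenotypic variance for trait {self.trait!r}")
        rm = _aligned(relationship, ids)
        d, U = rm.eigendecomposition()
        yr = U.T @ y
        Xr = U.T @ X
        n, p = X.shape

        self.identifiable_ = bool(np.ptp(d) > 1e-10)

        gamma_hi = 1.0 if d.min() > 1e-10 else 1.0 - 1e-6
        if self.va_zero or not self.identifiable_:
            gamma_hat = 0.0
        else:
            grid = np.linspace(0.0, gamma_hi, self.grid_size)
            vals = np.array(
                [_uni_profile_gamma(yr, Xr, d, g, self.method)[0] for g in grid]
            )
            k = int(np.argmax(vals))
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, len(grid) - 1)]
            if hi > lo:
                res = scipy.optimize.minimize_scalar(
                    lambda g: -_uni_profile_gamma(yr, Xr, d, g, self.method)[0],
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": self.tol},
                )
                gamma_hat = float(res.x)
                if _uni_profile_gamma(yr, Xr, d, gamma_hat, self.method)[0] < vals[k]:
                    gamma_hat = float(grid[k])
            else:  # pragma: no cover - degenerate grid
                gamma_hat = float(grid[k])
            # snap to the boundary when it is at least as good
            for bnd in (0.0, gamma_hi):
                if _uni_profile_gamma(yr, Xr, d, bnd, self.method)[0] >= \
                        _uni_profile_gamma(yr, Xr, d, gamma_hat, self.method)[0]:
                    gamma_hat = bnd

        ll, s2 = _uni_profile_gamma(yr, Xr, d, gamma_hat, self.method)
        va = gamma_hat * s2
        ve = (1.0 - gamma_hat) * s2
        self.boundary_ = bool(
            (not self.va_zero) and self.identifiable_
            and (gamma_hat <= 1e-8 or gamma_hat >= gamma_hi - 1e-8)
        )
        if gamma_hat <= 1e-8:
            va = 0.0
            ve = s2
        _, beta, XtWX = _uni_loglik_rotated(yr, Xr, d, max(va, 0.0), ve, self.method)

        self.VA_ = float(va)
        self.VE_ = float(ve)
        self.h2_ = float(va / (va + ve))
        self.loglik_ = float(ll)
        self.beta_ = pd.Series(beta, index=terms, name=self.trait)
        # Cov(beta) = s2 * (X' W^-1 X)^-1  (XtWX above is on the W=V/s2... no:
        # _uni_loglik_rotated uses V directly, so XtWX is X' V^-1 X already)
        cov_beta = np.linalg.inv(XtWX)
        self.beta_se_ = pd.Series(np.sqrt(np.diag(cov_beta)), index=terms)
        self._se_from_information(yr, Xr, d, va, ve)
        self.n_used_ = n
        self.ids_used_ = ids
        self.terms_ = terms
        return self

    def _se_from_information(self, yr, Xr, d, va, ve, rel_step=1e-4):
        """Observed information on (V_A, V_E) by central differences."""
        self.VA_se_ = self.VE_se_ = self.h2_se_ = float("nan")
        if self.boundary_ or self.va_zero or not self.identifiable_:
            return
        theta = np.array([va, ve])
        h = np.maximum(rel_step * np.abs(theta), 1e-8)

        def f(t):
            if t[0] < 0 or t[1] <= 0:
                return -np.inf
            try:
                return _uni_loglik_rotated(yr, Xr, d, t[0], t[1], self.method)[0]
            except (ValueError, np.linalg.LinAlgError):
                return -np.inf

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:  # pragma: no cover
            return
        if np.any(np.diag(cov) < 0):
            return
        self.VA_se_ = float(np.sqrt(cov[0, 0]))
        self.VE_se_ = float(np.sqrt(cov[1, 1]))
        tot = va + ve
        g = np.array([ve, -va]) / tot**2  # d h2 / d(V_A, V_E)
        self.h2_se_ = float(np.sqrt(g @ cov @ g))

    # small conveniences ------------------------------------------------
    def null_model(self) -> "UnivariateVarianceComponents":
        """The same model with V_A constrained to zero."""
        return UnivariateVarianceComponents(
            trait=self.trait,
            fixed_effects=self.fixed_effects,
            method=self.method,
            va_zero=True,
            grid_size=self.grid_size,
            tol=self.tol,
        )


# ---------------------------------------------------------------------------
# multivariate


def _chol_from_theta(theta: np.ndarray, T: int) -> np.ndarray:
    """Lower-triangular factor with exp-transformed diagonal."""
    L = np.zeros((T, T))
    k = 0
    for i in range(T):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    return L


def _theta_from_chol(L: np.ndarray) -> np.ndarray:
    T = L.shape[0]
    out = []
    for i in range(T):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _multi_nll_rotated(theta, Yr, Xr, d, T, method):
    """Negative profile log-likelihood in the eigenbasis (complete data)."""
    m = T * (T + 1) // 2
    LG = _chol_from_theta(theta[:m], T)
    LE = _chol_from_theta(theta[m:], T)
    G = LG @ LG.T
    E = LE @ LE.T
    n, p = Xr.shape
    S = d[:, None, None] * G + E  # (n, T, T)
    try:
        cholS = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return 1e12
    logdetV = 2.0 * float(np.sum(np.log(np.einsum("ikk->ik", cholS))))
    Sinv = np.linalg.inv(S)
    C = np.einsum("its,ip,iq->tpsq", Sinv, Xr, Xr).reshape(T * p, T * p)
    rhs = np.einsum("its,is,ip->tp", Sinv, Yr, Xr).reshape(T * p)
    try:
        cf = scipy.linalg.cho_factor(C)
    except (scipy.linalg.LinAlgError, ValueError):
        return 1e12
    beta = scipy.linalg.cho_solve(cf, rhs).reshape(T, p)
    R = Yr - Xr @ beta.T
    quad = float(np.einsum("it,its,is->", R, Sinv, R))
    N = n * T
    P = T * p
    if method == "reml":
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        nll = 0.5 * ((N - P) * _LOG2PI + logdetV + logdetC + quad)
    else:
        nll = 0.5 * (N * _LOG2PI + logdetV + quad)
    return nll


def _multi_beta_cov(G, E, Yr, Xr, d, T):
    """GLS beta, its covariance, and residuals at fixed (G, E)."""
    n, p = Xr.shape
    S = d[:, None, None] * G + E
    Sinv = np.linalg.inv(S)
    C = np.einsum("its,ip,iq->tpsq", Sinv, Xr, Xr).reshape(T * p, T * p)
    rhs = np.einsum("its,is,ip->tp", Sinv, Yr, Xr).reshape(T * p)
    Cinv = np.linalg.inv(C)
    beta = (Cinv @ rhs).reshape(T, p)
    return beta, Cinv


def _dense_blocks(A, G, E, obs_mask):
    """Covariance of the observed trait entries (individual-major layout)."""
    n, T = obs_mask.shape
    V = np.kron(A, G) + np.kron(np.eye(n), E)
    idx = np.flatnonzero(obs_mask.ravel())
    return V[np.ix_(idx, idx)], idx


def _multi_nll_dense(theta, Y, X, A, T, method):
    m = T * (T + 1) // 2
    LG = _chol_from_theta(theta[:m], T)
    LE = _chol_from_theta(theta[m:], T)
    G = LG @ LG.T
    E = LE @ LE.T
    ll = _dense_loglik(Y, X, A, G, E, method=method)
    return -ll if np.isfinite(ll) else 1e12


def _dense_loglik(Y, X, A, G, E, beta=None, method="reml"):
    """Observed-block log-likelihood; missing trait entries (NaN) dropped.

    With ``beta=None`` the fixed effects are profiled (GLS); an explicit
    ``beta`` (T x p) is honoured only under ML.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == 1 and Y.shape[1] != 1 and A.shape[0] != 1:
        Y = Y.T
    n, T = Y.shape
    obs = ~np.isnan(Y)
    V, idx = _dense_blocks(A, G, E, obs)
    p = X.shape[1]
    Xbig = np.kron(X, np.eye(T))  # row (i,t); col (q,s) -> beta[s,q]? see below
    # column ordering of kron(X, I_T): (q, s); we want beta stacked trait-major
    # beta_vec[(t,p)] -> build explicitly instead for clarity:
    Xbig = np.zeros((n * T, T * p))
    for t in range(T):
        for q in range(p):
            Xbig[t::T, t * p + q] = X[:, q]
    Xo = Xbig[idx]
    yo = Y.ravel()[idx]
    try:
        cf = scipy.linalg.cho_factor(V)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise ValueError("non-positive-definite total covariance")
    Vi_X = scipy.linalg.cho_solve(cf, Xo)
    C = Xo.T @ Vi_X
    N = len(yo)
    P = T * p
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if beta is None:
        ccf = scipy.linalg.cho_factor(C)
        bvec = scipy.linalg.cho_solve(ccf, Xo.T @ scipy.linalg.cho_solve(cf, yo))
    else:
        bvec = np.asarray(beta, float).reshape(T * p)
    r = yo - Xo @ bvec
    quad = float(r @ scipy.linalg.cho_solve(cf, r))
    if method == "reml":
        ccf = scipy.linalg.cho_factor(C)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(ccf[0]))))
        return -0.5 * ((N - P) * _LOG2PI + logdetV + logdetC + quad)
    return -0.5 * (N * _LOG2PI + logdetV + quad)


class MultivariateVarianceComponents(BaseEstimator):
    """Joint genetic/environmental covariance decomposition for 2-4 traits.

    Estimates ``G`` (additive genetic) and ``E`` (residual environmental)
    covariance matrices by REML through Cholesky-factor parameterisation,
    and reports their correlation forms ``rG_``/``rE_`` and per-trait
    heritabilities ``h2_``.  Individuals with some missing traits still
    contribute their observed block (dense path); with rectangular data the
    fit runs in the eigenbasis of A (fast path).
    """

    def __init__(
        self,
        traits: tuple = (),
        fixed_effects: tuple = (),
        method: str = "reml",
        max_iter: int = 500,
        tol: float = 1e-9,
    ):
        self.traits = traits
        self.fixed_effects = fixed_effects
        self.method = method
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, data, relationship: RelationshipMatrix):
        traits = list(self.traits)
        if len(traits) < 2:
            raise ModelDataError(
                "need >= 2 traits; use UnivariateVarianceComponents for one"
            )
        if len(traits) > 4:
            raise ModelDataError("at most 4 traits supported")
        Y, X, ids, terms = _build_design(
            data, traits, list(self.fixed_effects), False
        )
        T = len(traits)
        n, p = X.shape
        rm = _aligned(relationship, ids)
        complete = not np.isnan(Y).any()

        # deterministic initialisation: half the phenotypic variance on each
        # side, identity correlation structure
        v0 = np.array([np.nanvar(Y[:, t]) for t in range(T)])
        v0 = np.maximum(v0, 1e-12)
        L0 = np.diag(np.sqrt(v0 / 2.0))
        x0 = np.concatenate([_theta_from_chol(L0), _theta_from_chol(L0)])

        if complete:
            d, U = rm.eigendecomposition()
            Yr = U.T @ Y
            Xr = U.T @ X
            fun = lambda th: _multi_nll_rotated(th, Yr, Xr, d, T, self.method)
        else:
            fun = lambda th: _multi_nll_dense(th, Y, X, rm.A, T, self.method)

        # bounds keep the Cholesky parameters in a numerically safe range
        m = T * (T + 1) // 2
        diag_pos = []
        k = 0
        for i in range(T):
            for j in range(i + 1):
                if i == j:
                    diag_pos.append(k)
                k += 1
        scale = float(np.sqrt(v0.max()))
        bounds = []
        for half in range(2):
            for k in range(m):
                if k in diag_pos:
                    bounds.append((np.log(scale) - 25.0, np.log(scale) + 10.0))
                else:
                    bounds.append((-1e3 * scale, 1e3 * scale))
        res = scipy.optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": self.max_iter,
                "ftol": self.tol,
                "gtol": 1e-7,
                "maxfun": 20000,
            },
        )
        m = T * (T + 1) // 2
        LG = _chol_from_theta(res.x[:m], T)
        LE = _chol_from_theta(res.x[m:], T)
        G = LG @ LG.T
        E = LE @ LE.T
        self.converged_ = bool(res.success)
        self.loglik_ = float(-res.fun)
        self.G_ = pd.DataFrame(G, index=traits, columns=traits)
        self.E_ = pd.DataFrame(E, index=traits, columns=traits)

        def corr(M):
            s = np.sqrt(np.clip(np.diag(M), 1e-300, None))
            return M / np.outer(s, s)

        self.rG_ = pd.DataFrame(corr(G), index=traits, columns=traits)
        self.rE_ = pd.DataFrame(corr(E), index=traits, columns=traits)
        h2 = np.diag(G) / (np.diag(G) + np.diag(E))
        self.h2_ = pd.Series(h2, index=traits, name="h2")
        off = ~np.eye(T, dtype=bool)
        self.degenerate_ = bool(
            np.any(np.abs(self.rG_.to_numpy()[off]) > 1 - 1e-3)
            and np.any(np.abs(self.rE_.to_numpy()[off]) > 1 - 1e-3)
        )
        if complete:
            beta, Cinv = _multi_beta_cov(G, E, Yr, Xr, d, T)
        else:
            # one dense pass for beta at the optimum
            obs = ~np.isnan(Y)
            V, idx = _dense_blocks(rm.A, G, E, obs)
            Xbig = np.zeros((n * T, T * p))
            for t in range(T):
                for q in range(p):
                    Xbig[t::T, t * p + q] = X[:, q]
            Xo = Xbig[idx]
            yo = Y.ravel()[idx]
            cf = scipy.linalg.cho_factor(V)
            C = Xo.T @ scipy.linalg.cho_solve(cf, Xo)
            Cinv = np.linalg.inv(C)
            beta = (Cinv @ (Xo.T @ scipy.linalg.cho_solve(cf, yo))).reshape(T, p)
        self.beta_ = pd.DataFrame(beta, index=traits, columns=terms)
        se = np.sqrt(np.diag(Cinv)).reshape(T, p)
        self.beta_se_ = pd.DataFrame(se, index=traits, columns=terms)
        self.n_used_ = n
        self.ids_used_ = ids
        self.terms_ = terms
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def fit_univariate(
    data,
    relationship: RelationshipMatrix,
    trait: str,
    fixed_effects=(),
    method: str = "reml",
    va_zero: bool = False,
) -> UnivariateVarianceComponents:
    """Fit the additive + residual decomposition for one trait."""
    return UnivariateVarianceComponents(
        trait=trait, fixed_effects=tuple(fixed_effects), method=method,
        va_zero=va_zero,
    ).fit(data, relationship)


def fit_multivariate(
    data,
    relationship: RelationshipMatrix,
    traits,
    fixed_effects=(),
    method: str = "reml",
) -> MultivariateVarianceComponents:
    """Fit the joint G/E covariance decomposition for 2-4 traits."""
    return MultivariateVarianceComponents(
        traits=tuple(traits), fixed_effects=tuple(fixed_effects), method=method
    ).fit(data, relationship)


def loglik_direct(
    data,
    relationship: RelationshipMatrix,
    traits,
    fixed_effects=(),
    VA: float | None = None,
    VE: float | None = None,
    G=None,
    E=None,
    beta=None,
    method: str = "reml",
) -> float:
    """Exact dense log-likelihood at explicit covariance parameters.

    This is the slow, assumption-free evaluation the optimised fits are
    checked against: it builds the full covariance ``A (x) G + I (x) E``
    over the observed trait entries and evaluates the multivariate-normal
    (restricted) log density.  Non-positive-definite parameters raise.
    Univariate models pass ``VA``/``VE``; multivariate pass ``G``/``E``.
    ``beta`` (per-trait fixed effects) is honoured under ML; REML profiles
    the fixed effects by construction.
    """
    if isinstance(traits, str):
        traits = [traits]
    traits = list(traits)
    if G is None:
        if VA is None or VE is None:
            raise ValueError("supply VA and VE (univariate) or G and E")
        G = np.array([[float(VA)]])
        E = np.array([[float(VE)]])
        if len(traits) != 1:
            raise ValueError("scalar VA/VE with multiple traits")
    G = np.asarray(G, float)
    E = np.asarray(E, float)
    Y, X, ids, _ = _build_design(
        data, traits, list(fixed_effects), False, min_rows=1
    )
    rm = _aligned(relationship, ids)
    return float(_dense_loglik(Y, X, rm.A, G, E, beta=beta, method=method))


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    p: float


def lrt_heritability(fit_full, fit_null) -> LRTResult:
    """Boundary likelihood-ratio test of V_A = 0.

    The statistic ``2 (l_full - l_null)`` is clamped at 0 and referred to
    the boundary mixture ``0.5 chi2_0 + 0.5 chi2_1``.
    """
    if list(fit_full.terms_) != list(fit_null.terms_):
        raise ValueError("fixed-effect specifications differ between fits")
    if fit_full.method != fit_null.method:
        raise ValueError("estimation methods differ between fits")
    stat = max(0.0, 2.0 * (fit_full.loglik_ - fit_null.loglik_))
    p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return LRTResult(statistic=float(stat), p=float(p))


def wald_fixed_effects(fit) -> pd.DataFrame:
    """Per-term estimate, asymptotic SE and two-sided normal p-value."""
    beta = fit.beta_
    se = fit.beta_se_
    if isinstance(beta, pd.DataFrame):  # multivariate: stack trait-major
        rows = []
        for t in beta.index:
            for term in beta.columns:
                rows.append((t, term, beta.loc[t, term], se.loc[t, term]))
        out = pd.DataFrame(rows, columns=["trait", "term", "estimate", "ase"])
    else:
        out = pd.DataFrame(
            {"term": beta.index, "estimate": beta.values, "ase": se.values}
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = out["estimate"] / out["ase"]
    out["p"] = 2.0 * norm.sf(np.abs(z))
    out.loc[out["estimate"] == 0.0, "p"] = 1.0
    return out
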