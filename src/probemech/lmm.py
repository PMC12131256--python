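"""Random-intercept linear mixed model with REML estimation and Satterthwaite df.

The only random-effects structure the analysis needs is a single random
intercept per grouping unit (the individual plant), i.e.

    y = X beta + Z b + e,   b ~ N(0, tau2 I),   e ~ N(0, sigma2 I)

with Z the group indicator matrix. For this structure the marginal covariance
is block diagonal with blocks sigma2 I + tau2 J, so the REML criterion,
GLS estimates and their covariance all have closed per-group forms; the
variance ratio gamma = tau2/sigma2 is profiled and optimised in one
dimension. Denominator degrees of freedom for Wald t and F tests use the
Satterthwaite approximation: for a contrast l,

    df = 2 (l' C l)^2 / (g' A g)

where C = Cov(beta_hat), g is the gradient of l' C(theta) l with respect to
the variance parameters and A the asymptotic covariance of theta_hat (twice
the inverse Hessian of the -2 restricted log-likelihood). Multi-degree F
tests decompose the hypothesis into independent one-dimensional contrasts
via the eigenstructure of L C L' and pool their per-contrast df.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMError", "FTest", "RandomInterceptLMM"]

_SINGULAR_GAMMA = 1e-8


class LMMError(ValueError):
    pass


@dataclass(frozen=True)
class FTest:
    fvalue: float
    df_num: float
    df_den: float
    pvalue: float


class RandomInterceptLMM:
    """REML fit of ``y = X beta + (1 | group) + e``.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effects design, full column rank
    groups : (n,) group labels (any hashable)
    exog_names : column labels for X
    """

    def __init__(self, y, X, groups, exog_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise LMMError("X must be 2-D with rows matching y")
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise LMMError("need more observations than fixed-effect columns")
        if np.linalg.matrix_rank(self.X) < self.p:
            raise LMMError("fixed-effects design is rank deficient")
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(self.p)]
        )
        # centre y through an intercept column (if any): a constant shift of
        # the response then leaves the optimisation path bit-identical
        self._icol = next(
            (j for j in range(self.p) if np.all(self.X[:, j] == 1.0)), None
        )
        self._ybar = float(self.y.mean()) if self._icol is not None else 0.0
        self.y = self.y - self._ybar
        codes, uniques = np.unique(np.asarray(groups), return_inverse=True)
        self.group_labels = codes
        self._gidx = [np.flatnonzero(uniques == k) for k in range(len(codes))]
        self.n_groups = len(codes)

        # fitted state
        self.fitted = False
        self.sigma2: float = math.nan
        self.tau2: float = math.nan
        self.beta: np.ndarray | None = None
        self.cov_beta: np.ndarray | None = None
        self.singular: bool = False
        self._theta_cov: np.ndarray | None = None  # asymptotic Cov(sigma2, tau2)

    # -- closed-form per-group algebra -------------------------------------

    def _gls_pieces(self, gamma: float):
        """X'WX, X'Wy and sum log(1 + n_i gamma) for W = (V/sigma2)^-1."""
        X, y = self.X, self.y
        xtx = X.T @ X
        xty = X.T @ y
        logdet = 0.0
        for idx in self._gidx:
            ni = len(idx)
            c = gamma / (1.0 + ni * gamma)
            sx = X[idx].sum(axis=0)
            sy = float(y[idx].sum())
            xtx -= c * np.outer(sx, sx)
            xty -= c * sx * sy
            logdet += math.log1p(ni * gamma)
        return xtx, xty, logdet

    def _weighted_rss(self, beta: np.ndarray, gamma: float) -> float:
        """r' W r via explicit residuals (stable under constant shifts of y)."""
        resid = self.y - self.X @ beta
        rss = 0.0
        for idx in self._gidx:
            ni = len(idx)
            c = gamma / (1.0 + ni * gamma)
            r = resid[idx]
            rss += float(r @ r) - c * float(r.sum()) ** 2
        return rss

    def _profiled_neg2_reml(self, log_gamma: float) -> float:
        gamma = math.exp(log_gamma)
        xtx, xty, logdet = self._gls_pieces(gamma)
        try:
            beta = np.linalg.solve(xtx, xty)
            sign, logdet_xtx = np.linalg.slogdet(xtx)
        except np.linalg.LinAlgError:
            return math.inf
        if sign <= 0:
            return math.inf
        rss = self._weighted_rss(beta, gamma)
        if rss <= 0:
            return math.inf
        df = self.n - self.p
        return df * math.log(rss / df) + logdet + logdet_xtx

    def _neg2_reml_full(self, theta: np.ndarray) -> float:
        """-2 restricted log-likelihood at unprofiled theta = (sigma2, tau2)."""
        sigma2, tau2 = float(theta[0]), float(theta[1])
        if sigma2 <= 0 or tau2 < 0:
            return math.inf
        gamma = tau2 / sigma2
        xtx, xty, logdet = self._gls_pieces(gamma)
        beta = np.linalg.solve(xtx, xty)
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        rss = self._weighted_rss(beta, gamma)
        df = self.n - self.p
        # log|V| = n log sigma2 + sum log(1+n_i gamma);
        # log|X'V^-1 X| = logdet_xtx - p log sigma2; r'V^-1 r = rss / sigma2
        return (
            self.n * math.log(sigma2)
            + logdet
            + logdet_xtx
            - self.p * math.log(sigma2)
            + rss / sigma2
        )

    def _cov_beta_at(self, theta: np.ndarray) -> np.ndarray:
        sigma2, tau2 = float(theta[0]), float(theta[1])
        gamma = max(tau2, 0.0) / sigma2
        xtx, _, _ = self._gls_pieces(gamma)
        return sigma2 * np.linalg.inv(xtx)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "RandomInterceptLMM":
        res = optimize.minimize_scalar(
            self._profiled_neg2_reml,
            bounds=(-20.0, 20.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        # Newton polish: Brent stops anywhere inside the noise-flat basin, so
        # pin the optimum down via the local quadratic (deterministic to ~1e-9)
        u = res.x
        h = 1e-4
        for _ in range(12):
            fp, fm, f0 = (
                self._profiled_neg2_reml(u + h),
                self._profiled_neg2_reml(u - h),
                self._profiled_neg2_reml(u),
            )
            curv = (fp - 2 * f0 + fm) / h**2
            if not math.isfinite(curv) or curv <= 0:
                break
            step = (fp - fm) / (2 * h) / curv
            step = max(min(step, 0.5), -0.5)
            u -= step
            if abs(step) < 1e-10:
                break
        gamma = math.exp(u)
        # the boundary gamma -> 0 (no plant variance) must be checked
        # explicitly; a flat criterion (unidentifiable split) also lands here
        if self._profiled_neg2_reml(-300.0) <= min(res.fun, self._profiled_neg2_reml(u)) + 1e-6:
            gamma = 0.0
        xtx, xty, _ = self._gls_pieces(gamma)
        beta = np.linalg.solve(xtx, xty)
        rss = self._weighted_rss(beta, gamma)
        self.sigma2 = rss / (self.n - self.p)
        self.tau2 = gamma * self.sigma2
        if self._icol is not None:
            beta = beta.copy()
            beta[self._icol] += self._ybar
        self.beta = beta
        self.cov_beta = self.sigma2 * np.linalg.inv(xtx)
        self.singular = gamma < _SINGULAR_GAMMA
        if self.singular:
            warnings.warn(
                "singular fit: plant-level variance estimated at zero; "
                "Wald tests fall back to residual degrees of freedom",
                stacklevel=2,
            )
            self._theta_cov = None
        else:
            self._theta_cov = self._estimate_theta_cov()
        self.fitted = True
        return self

    def _estimate_theta_cov(self) -> np.ndarray | None:
        """2 * inverse Hessian of -2 restricted loglik at theta_hat (log scale FD)."""
        theta = np.array([self.sigma2, self.tau2])
        u0 = np.log(theta)
        h = 1e-5

        def f(u):
            return self._neg2_reml_full(np.exp(u))

        H = np.empty((2, 2))
        f0 = f(u0)
        for i in range(2):
            ei = np.zeros(2)
            ei[i] = h
            H[i, i] = (f(u0 + ei) - 2 * f0 + f(u0 - ei)) / h**2
        e0 = np.array([h, 0.0])
        e1 = np.array([0.0, h])
        H[0, 1] = H[1, 0] = (
            f(u0 + e0 + e1) - f(u0 + e0 - e1) - f(u0 - e0 + e1) + f(u0 - e0 - e1)
        ) / (4 * h**2)
        try:
            cov_u = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov_u)) or cov_u[0, 0] <= 0 or cov_u[1, 1] <= 0:
            return None
        # delta rule back to the variance scale: d theta / d u = diag(theta)
        J = np.diag(theta)
        return J @ cov_u @ J

    def _require_fit(self) -> None:
        if not self.fitted:
            raise LMMError("model is not fitted; call fit() first")

    # -- inference ----------------------------------------------------------

    def _grad_contrast_var(self, ell: np.ndarray) -> np.ndarray:
        """Gradient of l' C(theta) l wrt theta = (sigma2, tau2), central FD."""
        theta = np.array([self.sigma2, self.tau2])
        g = np.empty(2)
        for i in range(2):
            h = 1e-6 * max(theta[i], 1e-12)
            tp = theta.copy()
            tm = theta.copy()
            tp[i] += h
            tm[i] = max(tm[i] - h, 0.0 if i == 1 else 1e-300)
            vp = float(ell @ self._cov_beta_at(tp) @ ell)
            vm = float(ell @ self._cov_beta_at(tm) @ ell)
            g[i] = (vp - vm) / (tp[i] - tm[i])
        return g

    def contrast_df(self, ell: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast l' beta."""
        self._require_fit()
        ell = np.asarray(ell, dtype=float)
        if self.singular or self._theta_cov is None:
            return float(self.n - self.p)
        v = float(ell @ self.cov_beta @ ell)
        g = self._grad_contrast_var(ell)
        denom = float(g @ self._theta_cov @ g)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * v * v / denom
        return float(min(df, self.n - self.p)) if df > 0 else float(self.n - self.p)

    def t_test(self, ell: np.ndarray) -> tuple[float, float, float, float]:
        """(estimate, se, t, df) for the contrast l' beta."""
        self._require_fit()
        ell = np.asarray(ell, dtype=float)
        est = float(ell @ self.beta)
        se = math.sqrt(float(ell @ self.cov_beta @ ell))
        df = self.contrast_df(ell)
        t = est / se if se > 0 else math.nan
        return est, se, t, df

    def f_test(self, L: np.ndarray) -> FTest:
        """Wald F test of L beta = 0 with pooled Satterthwaite denominator df."""
        self._require_fit()
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        LCL = L @ self.cov_beta @ L.T
        Lb = L @ self.beta
        F = float(Lb @ np.linalg.solve(LCL, Lb)) / q

        if self.singular or self._theta_cov is None:
            ddf = float(self.n - self.p)
        else:
            # decompose into q independent contrasts and pool their df
            evals, evecs = np.linalg.eigh(LCL)
            dfs = []
            for m in range(q):
                if evals[m] <= 1e-14 * max(evals.max(), 1.0):
                    continue
                ell = evecs[:, m] @ L
                dfs.append(self.contrast_df(ell))
            if not dfs:
                ddf = float(self.n - self.p)
            else:
                terms = [nu / (nu - 2.0) for nu in dfs if nu > 2.0]
                if len(terms) < len(dfs) or not terms:
                    ddf = float(self.n - self.p)
                else:
                    E = sum(terms)
                    ddf = 2.0 * E / (E - q) if E > q else float(self.n - self.p)
        p = float(stats.f.sf(F, q, ddf))
        return FTest(fvalue=F, df_num=float(q), df_den=float(ddf), pvalue=p)
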