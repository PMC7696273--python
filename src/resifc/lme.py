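"""Random-intercept linear mixed models, vectorized over many responses.

The model is y = X beta + Z u + e with one random intercept per group
(subject), u ~ N(0, sigma_u^2 I), e ~ N(0, sigma_e^2 I).  Estimation is
restricted maximum likelihood, profiled over the variance ratio
lambda = sigma_u^2 / sigma_e^2.  Because Z Z' is block-diagonal in the
subject blocks, whitening, log-determinants and the information matrix all
reduce to per-subject scalar aggregates, which lets thousands of voxel
responses sharing one design be fitted in a few matrix products.

Inference uses t statistics with Satterthwaite degrees of freedom computed
from the REML information matrix of (sigma_e^2, sigma_u^2); for a fixed
design the df of a contrast depends only on the selected lambda, so it is
shared across voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import t as t_dist

__all__ = ["RandomInterceptLME", "RandomInterceptFit", "ContrastResult"]

#: profiled variance-ratio grid used for vectorized fits
DEFAULT_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-4, 4, 81)])

#: lambda at/below which a fit is flagged singular (variance ~ 0)
SINGULAR_LAMBDA = 1e-6


@dataclass
class ContrastResult:
    estimate: np.ndarray
    se: np.ndarray
    df: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray


class RandomInterceptLME:
    """REML machinery for a fixed design ``X`` and grouping vector."""

    def __init__(self, X: np.ndarray, groups, columns: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.X = X
        self.n, self.p = X.shape
        codes, uniques = pd.factorize(np.asarray(groups), sort=True)
        if len(codes) != self.n:
            raise ValueError("groups length must match rows of X")
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.q = len(uniques)
        self.counts = np.bincount(codes, minlength=self.q).astype(float)
        if self.q < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        self.columns = columns or [f"x{i}" for i in range(self.p)]
        # per-group row sums of X: q x p
        self.G = np.zeros((self.q, self.p))
        np.add.at(self.G, codes, X)
        self.XtX = X.T @ X
        s = np.linalg.svd(X, compute_uv=False)
        if s[-1] < 1e-10 * s[0]:
            raise np.linalg.LinAlgError("fixed-effects design is rank deficient")
        self._cache: dict[float, dict] = {}

    # -- per-lambda shared quantities ------------------------------------
    def _group_mean(self, M: np.ndarray) -> np.ndarray:
        sums = np.zeros((self.q,) + M.shape[1:])
        np.add.at(sums, self.group_codes, M)
        return sums / self.counts.reshape((self.q,) + (1,) * (M.ndim - 1))

    def whiten(self, M: np.ndarray, lam: float) -> np.ndarray:
        """Apply (I + lam ZZ')^{-1/2} to the rows of M."""
        u = 1.0 / (1.0 + lam * self.counts)
        shrink = (1.0 - np.sqrt(u))[self.group_codes].reshape((-1,) + (1,) * (M.ndim - 1))
        return M - shrink * self._group_mean(M)[self.group_codes]

    def _stats(self, lam: float) -> dict:
        st = self._cache.get(lam)
        if st is not None:
            return st
        u = 1.0 / (1.0 + lam * self.counts)  # per-group shrinkage eigenvalue
        Xw = self.whiten(self.X, lam)
        C = Xw.T @ Xw  # X' B X
        Cinv = np.linalg.inv(C)
        sign, logdet_C = np.linalg.slogdet(C)
        st = {
            "lam": lam,
            "u": u,
            "Xw": Xw,
            "C": C,
            "Cinv": Cinv,
            "logdet_C": logdet_C,
            "logdet_V": -np.log(u).sum(),
        }
        self._cache[lam] = st
        if len(self._cache) > 256:
            self._cache.pop(next(iter(self._cache)))
        return st

    def _xbk(self, u: np.ndarray, k: int) -> np.ndarray:
        """X' B^k X via the block eigenstructure."""
        w = (1.0 - u**k) / self.counts
        return self.XtX - (self.G * w[:, None]).T @ self.G

    # -- REML criterion ---------------------------------------------------
    def reml_criterion(self, lam: float, Y: np.ndarray) -> np.ndarray:
        """-2 restricted log-likelihood up to a constant, per response column."""
        st = self._stats(lam)
        Yw = self.whiten(Y if Y.ndim == 2 else Y[:, None], lam)
        beta = st["Cinv"] @ (st["Xw"].T @ Yw)
        rss = ((Yw - st["Xw"] @ beta) ** 2).sum(axis=0)
        rss = np.maximum(rss, 1e-300)
        return (self.n - self.p) * np.log(rss) + st["logdet_V"] + st["logdet_C"]

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        Y: np.ndarray,
        lambda_grid: np.ndarray | None = None,
        refine: bool | None = None,
    ) -> "RandomInterceptFit":
        """Profile-REML fit.

        ``Y`` may be 1-D (one response; lambda refined by bounded scalar
        minimization) or 2-D ``(n, V)`` (many responses; lambda selected per
        column on a shared grid).
        """
        Y = np.asarray(Y, dtype=float)
        single = Y.ndim == 1
        Ymat = Y[:, None] if single else Y
        if Ymat.shape[0] != self.n:
            raise ValueError("response length must match the design")
        grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
        crits = np.stack([self.reml_criterion(lam, Ymat) for lam in grid])
        best = np.argmin(crits, axis=0)
        lam_hat = grid[best]
        if refine is None:
            refine = single
        if refine:
            lam_hat = lam_hat.copy()
            for j in range(Ymat.shape[1]):
                i = best[j]
                lo = grid[max(i - 1, 0)]
                hi = grid[min(i + 1, len(grid) - 1)]
                if hi > lo:
                    y = Ymat[:, j]
                    res = optimize.minimize_scalar(
                        lambda lv: float(self.reml_criterion(lv, y[:, None])[0]),
                        bounds=(lo, hi),
                        method="bounded",
                        options={"xatol": 1e-10},
                    )
                    if res.fun <= crits[i, j]:
                        lam_hat[j] = res.x
        return RandomInterceptFit(model=self, Y=Ymat, lam=lam_hat, single=single)


@dataclass
class RandomInterceptFit:
    model: RandomInterceptLME
    Y: np.ndarray = field(repr=False)
    lam: np.ndarray
    single: bool

    def __post_init__(self) -> None:
        m = self.model
        V = self.Y.shape[1]
        self.beta = np.empty((m.p, V))
        self.sigma_e2 = np.empty(V)
        for lam in np.unique(self.lam):
            st = m._stats(lam)
            cols = np.flatnonzero(self.lam == lam)
            Yw = m.whiten(self.Y[:, cols], lam)
            b = st["Cinv"] @ (st["Xw"].T @ Yw)
            self.beta[:, cols] = b
            rss = ((Yw - st["Xw"] @ b) ** 2).sum(axis=0)
            self.sigma_e2[cols] = rss / (m.n - m.p)
        self.sigma_u2 = self.lam * self.sigma_e2
        self.singular = self.lam <= SINGULAR_LAMBDA
        if self.single and self.singular[0]:
            warnings.warn(
                "random-intercept variance estimated at the zero boundary (singular fit)",
                stacklevel=2,
            )

    # -- Satterthwaite machinery -----------------------------------------
    def _satterthwaite_parts(self, lam: float, c: np.ndarray) -> tuple[float, float]:
        """(f1, df) for contrast c at variance ratio lam.

        f1 = c' C^{-1} c is the unscaled contrast variance (Var = sigma_e^2 f1);
        df is the Satterthwaite degrees of freedom, which for this model is
        free of sigma_e^2 and therefore shared by all responses with this lam.
        """
        m = self.model
        st = m._stats(lam)
        u, Cinv = st["u"], st["Cinv"]
        D1 = m._xbk(u, 2)  # X' B^2 X
        D2 = ((m.G * (u**2)[:, None]).T @ m.G)  # X' B ZZ' B X
        Cc = Cinv @ c
        f1 = float(c @ Cc)
        g = np.array([float(Cc @ D1 @ Cc), float(Cc @ D2 @ Cc)])
        # information-matrix traces (unscaled by sigma_e^4)
        tr_B2 = (m.n - m.q) + (u**2).sum()
        XB3X = m._xbk(u, 3)
        t11 = tr_B2 - 2.0 * np.trace(Cinv @ XB3X) + np.trace(Cinv @ D1 @ Cinv @ D1)
        ug = m.G * u[:, None]
        M = np.diag(u * m.counts) - ug @ Cinv @ ug.T
        t22 = float((M**2).sum())
        gC = np.einsum("sp,pq,sq->s", m.G, Cinv, m.G)  # g_s' C^-1 g_s
        gD = np.einsum("sp,pq,qr,rt,st->s", m.G, Cinv, D1, Cinv, m.G)
        t12 = float((u**2 * (m.counts - 2.0 * u * gC + gD)).sum())
        T = np.array([[t11, t12], [t12, t22]])
        try:
            denom = float(g @ np.linalg.solve(T, g))
        except np.linalg.LinAlgError:
            denom = np.inf
        if denom <= 0 or not np.isfinite(denom):
            df = float(m.n - m.p)
        else:
            df = f1**2 / denom
            df = min(df, float(m.n - m.p))
        return f1, df

    def contrast(self, c: np.ndarray) -> ContrastResult:
        """Estimate, SE, Satterthwaite df and two-sided p for c' beta."""
        c = np.asarray(c, dtype=float)
        if c.shape != (self.model.p,):
            raise ValueError(f"contrast must have length {self.model.p}")
        V = self.Y.shape[1]
        est = c @ self.beta
        se = np.empty(V)
        df = np.empty(V)
        for lam in np.unique(self.lam):
            cols = np.flatnonzero(self.lam == lam)
            f1, dfl = self._satterthwaite_parts(lam, c)
            se[cols] = np.sqrt(self.sigma_e2[cols] * f1)
            df[cols] = dfl
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        pval = 2.0 * t_dist.sf(np.abs(tstat), df)
        if self.single:
            return ContrastResult(est[0], se[0], df[0], tstat[0], pval[0])
        return ContrastResult(est, se, df, tstat, pval)

    def contrast_covariance(self, contrasts: np.ndarray) -> np.ndarray:
        """Covariance matrix of L beta (rows of ``contrasts``), single response only."""
        if not self.single:
            raise ValueError("contrast_covariance supports single-response fits only")
        lam = float(self.lam[0])
        st = self.model._stats(lam)
        L = np.asarray(contrasts, dtype=float)
        return float(self.sigma_e2[0]) * (L @ st["Cinv"] @ L.T)

    def fixed_effects(self) -> pd.DataFrame:
        """Per-coefficient table (single response only)."""
        if not self.single:
            raise ValueError("fixed_effects table supports single-response fits only")
        rows = []
        for i, name in enumerate(self.model.columns):
            c = np.zeros(self.model.p)
            c[i] = 1.0
            r = self.contrast(c)
            rows.append(
                {
                    "term": name,
                    "estimate": float(r.estimate),
                    "se": float(r.se),
                    "df": float(r.df),
                    "tstat": float(r.tstat),
                    "pvalue": float(r.pvalue),
                }
            )
        return pd.DataFrame(rows)

    def loglik_reml(self) -> np.ndarray:
        """Full REML log-likelihood (with constants), per response."""
        m = self.model
        out = np.empty(self.Y.shape[1])
        for lam in np.unique(self.lam):
            st = m._stats(lam)
            cols = np.flatnonzero(self.lam == lam)
            s2 = self.sigma_e2[cols]
            nmp = m.n - m.p
            out[cols] = -0.5 * (
                nmp * np.log(2.0 * np.pi * s2) + nmp + st["logdet_V"] + st["logdet_C"]
            )
        return out
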