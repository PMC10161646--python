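"""Genomic heritability and genetic correlation via REML.

``HeritabilityModel`` fits the single-trait animal model
``y = X b + g + e``, ``g ~ N(0, sg2 G)``, by one-dimensional profile REML
over the variance ratio (see :mod:`splicecross.reml`). Significance of the
additive component comes from a likelihood-ratio test of the full model
against the no-genetic-variance reduction, with the null distribution the
50:50 mixture of a point mass at zero and chi-square(1) appropriate for a
variance parameter on the boundary.

``GeneticCorrelationModel`` fits the bivariate animal model with 2x2 genetic
and residual covariance matrices (log-Cholesky parameterised, quasi-Newton
optimised) and reports r_G with a likelihood-ratio test of sigma_g12 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .reml import ProjectedKernel, reml_loglik, reml_profile


def _design(n: int, covariates=None) -> np.ndarray:
    """Intercept plus optional covariate columns."""
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    return X


def sex_covariate(sex) -> np.ndarray:
    """0/1 indicator for male, the standard fixed effect in this package."""
    return (np.asarray(sex, dtype=object) == "M").astype(float)


def _boundary_mixture_p(stat: float) -> float:
    return float(0.5 * chi2.sf(stat, 1)) if stat > 0 else 0.5


def heritability_lrt(
    llf_full: float, llf_null: float, boundary_mixture: bool = True
) -> tuple[float, float]:
    """Boundary LRT: statistic clipped at 0; p from the 0.5 chi2_0 + 0.5 chi2_1
    mixture by default, plain chi2_1 with ``boundary_mixture=False``."""
    stat = max(0.0, 2.0 * (llf_full - llf_null))
    p = _boundary_mixture_p(stat) if boundary_mixture else float(chi2.sf(stat, 1))
    return stat, p


@dataclass
class VarCompResults:
    """Variance-component estimates for one trait."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    llf: float
    llf_null: float
    lrt: float
    pvalue: float
    nobs: int
    converged: bool
    identifiable: bool

    def summary(self) -> str:
        lines = [
            "Genomic heritability (profile REML)",
            "-" * 38,
            f"n observations      {self.nobs:>10d}",
            f"sigma^2_g           {self.sigma_g2:>10.4f}",
            f"sigma^2_e           {self.sigma_e2:>10.4f}",
            f"h^2                 {self.h2:>10.4f}",
            f"restricted logL     {self.llf:>10.3f}",
            f"LRT (h^2 = 0)       {self.lrt:>10.3f}",
            f"p (boundary mix)    {self.pvalue:>10.3g}",
        ]
        if not self.identifiable:
            lines.append("warning: GRM spectrum ~ constant; h^2 not identifiable")
        if not self.converged:
            lines.append("warning: optimizer did not report convergence")
        return "\n".join(lines)


class HeritabilityModel:
    """Single-trait animal model; ``fit()`` returns :class:`VarCompResults`.

    Parameters
    ----------
    endog : array-like
        Trait values; NaN rows are dropped jointly with the design.
    grm : DataFrame or ndarray
        Genomic relationship matrix aligned to the samples of ``endog``.
    covariates : array-like, optional
        Fixed-effect columns (e.g. the sex indicator); an intercept is
        always included.
    """

    def __init__(self, endog, grm, covariates=None):
        y = np.asarray(endog, dtype=float)
        G = grm.values if isinstance(grm, pd.DataFrame) else np.asarray(grm, dtype=float)
        if G.shape[0] != G.shape[1] or G.shape[0] != y.shape[0]:
            raise ValueError("GRM must be square and aligned to the trait")
        X = _design(len(y), covariates)
        keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
        if np.isinf(y[~np.isnan(y)]).any():
            raise ValueError("trait contains infinite values")
        self.endog = y[keep]
        self.exog = X[keep]
        self.grm = G[np.ix_(keep, keep)]
        if self.endog.shape[0] < self.exog.shape[1] + 2:
            raise ValueError("too few observations for the design")
        self._kernel: ProjectedKernel | None = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, grm: pd.DataFrame,
                       covariate_cols: list[str] | None = None):
        samples = [s for s in data.index if s in grm.index]
        sub = data.loc[samples]
        cov = None
        if covariate_cols:
            cols = []
            for c in covariate_cols:
                v = sub[c]
                cols.append(sex_covariate(v) if v.dtype == object else v.to_numpy(float))
            cov = np.column_stack(cols)
        return cls(sub[trait].to_numpy(float), grm.loc[samples, samples], cov)

    @property
    def kernel(self) -> ProjectedKernel:
        if self._kernel is None:
            self._kernel = ProjectedKernel.build(self.grm, self.exog)
        return self._kernel

    def loglike(self, lam: float) -> float:
        """Profiled restricted log-likelihood at variance ratio lam."""
        omega = self.kernel.rotate(self.endog)
        return reml_loglik(omega**2, self.kernel.theta, lam)

    def fit(self) -> VarCompResults:
        kern = self.kernel
        omega = kern.rotate(self.endog)
        lam, llf, se2, converged = reml_profile(omega, kern.theta)
        llf0 = reml_loglik(omega**2, kern.theta, 0.0)
        stat = max(0.0, 2.0 * (llf - llf0))
        sg2 = lam * se2
        h2 = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0
        identifiable = kern.identifiable
        if not identifiable:
            h2, sg2 = float("nan"), float("nan")
        return VarCompResults(
            sigma_g2=sg2,
            sigma_e2=se2,
            h2=h2,
            llf=llf,
            llf_null=llf0,
            lrt=stat,
            pvalue=_boundary_mixture_p(stat),
            nobs=self.endog.shape[0],
            converged=converged,
            identifiable=identifiable,
        )


def reml_fit(y, covariates, grm) -> VarCompResults:
    """Functional wrapper around :class:`HeritabilityModel`."""
    return HeritabilityModel(y, grm, covariates).fit()


def fit_heritability_matrix(
    traits: pd.DataFrame, grm: pd.DataFrame, covariates=None
) -> pd.DataFrame:
    """Per-row heritability for a traits x samples matrix; adds BH q-values."""
    rows = {}
    for tid, row in traits.iterrows():
        y = row.reindex(grm.index).to_numpy(dtype=float)
        try:
            res = HeritabilityModel(y, grm.values, covariates).fit()
        except ValueError:
            continue
        rows[tid] = {
            "sigma_g2": res.sigma_g2, "sigma_e2": res.sigma_e2, "h2": res.h2,
            "logL": res.llf, "LRT": res.lrt, "p": res.pvalue, "n": res.nobs,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Bivariate REML / genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneticCorrResults:
    r_g: float
    se: float
    r_e: float
    sigma_g: np.ndarray  # 2x2 genetic covariance
    sigma_e: np.ndarray  # 2x2 residual covariance
    llf: float
    llf_null: float
    lrt: float
    pvalue: float
    nobs: int
    defined: bool

    def summary(self) -> str:
        lines = [
            "Bivariate REML genetic correlation",
            "-" * 38,
            f"n observations      {self.nobs:>10d}",
            f"r_G                 {self.r_g:>10.4f}  (SE {self.se:.4f})",
            f"r_E                 {self.r_e:>10.4f}",
            f"LRT (sigma_g12=0)   {self.lrt:>10.3f}",
            f"p                   {self.pvalue:>10.3g}",
        ]
        if not self.defined:
            lines.append("warning: a genetic variance is ~0; r_G undefined")
        return "\n".join(lines)


def _chol_from_params(p3: np.ndarray) -> np.ndarray:
    C = np.array([[np.exp(p3[0]), 0.0], [p3[1], np.exp(p3[2])]])
    return C @ C.T


class GeneticCorrelationModel:
    """Bivariate animal model for two traits sharing one GRM."""

    def __init__(self, endog1, endog2, grm, covariates=None, min_overlap: int = 30):
        y1 = np.asarray(endog1, dtype=float)
        y2 = np.asarray(endog2, dtype=float)
        G = grm.values if isinstance(grm, pd.DataFrame) else np.asarray(grm, dtype=float)
        X = _design(len(y1), covariates)
        keep = np.isfinite(y1) & np.isfinite(y2) & np.isfinite(X).all(axis=1)
        if keep.sum() < min_overlap:
            raise ValueError(f"need >= {min_overlap} jointly observed samples")
        self.Y = np.column_stack([y1[keep], y2[keep]])
        # standardize for optimizer conditioning; r_G is scale invariant
        self.Y = (self.Y - self.Y.mean(0)) / self.Y.std(0, ddof=1)
        self.X = X[keep]
        d, U = eigh(G[np.ix_(keep, keep)])
        self.d = np.clip(d, 0.0, None)
        self.Ys = U.T @ self.Y
        self.Xs = U.T @ self.X
        self.n, self.p = self.X.shape

    def _neg_llf(self, params: np.ndarray, constrained: bool) -> float:
        if constrained:
            Sg = np.diag([np.exp(2 * params[0]), np.exp(2 * params[1])])
            pe = params[2:]
        else:
            Sg = _chol_from_params(params[:3])
            pe = params[3:]
        Se = _chol_from_params(pe)
        d = self.d
        v11 = d * Sg[0, 0] + Se[0, 0]
        v22 = d * Sg[1, 1] + Se[1, 1]
        v12 = d * Sg[0, 1] + Se[0, 1]
        det = v11 * v22 - v12**2
        if np.any(det <= 0) or np.any(v11 <= 0):
            return 1e10
        w11 = v22 / det
        w22 = v11 / det
        w12 = -v12 / det
        X, Y = self.Xs, self.Ys
        # GLS normal equations for stacked (beta1, beta2)
        A11 = X.T @ (X * w11[:, None])
        A22 = X.T @ (X * w22[:, None])
        A12 = X.T @ (X * w12[:, None])
        A = np.block([[A11, A12], [A12.T, A22]])
        b1 = X.T @ (w11 * Y[:, 0] + w12 * Y[:, 1])
        b2 = X.T @ (w12 * Y[:, 0] + w22 * Y[:, 1])
        if not np.all(np.isfinite(A)):
            return 1e10
        try:
            beta = np.linalg.solve(A, np.concatenate([b1, b2]))
        except np.linalg.LinAlgError:
            return 1e10
        r1 = Y[:, 0] - X @ beta[: self.p]
        r2 = Y[:, 1] - X @ beta[self.p:]
        quad = np.sum(w11 * r1**2 + 2 * w12 * r1 * r2 + w22 * r2**2)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e10
        llf = -0.5 * (np.sum(np.log(det)) + logdetA + quad)
        return -llf

    def _optimize(self, constrained: bool):
        # warm start near the univariate structure
        if constrained:
            x0 = np.array([-0.5, -0.5, -0.25, 0.0, -0.25])
        else:
            x0 = np.array([-0.5, 0.0, -0.5, -0.25, 0.0, -0.25])
        res = minimize(
            self._neg_llf, x0, args=(constrained,), method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        return res

    def fit(self, n_se_eps: float = 1e-4) -> GeneticCorrResults:
        full = self._optimize(constrained=False)
        null = self._optimize(constrained=True)
        Sg = _chol_from_params(full.x[:3])
        Se = _chol_from_params(full.x[3:])
        defined = bool(Sg[0, 0] > 1e-8 and Sg[1, 1] > 1e-8)
        rg = Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]) if defined else float("nan")
        re_ = Se[0, 1] / np.sqrt(Se[0, 0] * Se[1, 1])
        stat = max(0.0, 2.0 * (-full.fun - -null.fun))
        se = self._rg_se(full.x, n_se_eps) if defined else float("nan")
        return GeneticCorrResults(
            r_g=float(np.clip(rg, -1.0, 1.0)) if defined else float("nan"),
            se=se,
            r_e=float(np.clip(re_, -1.0, 1.0)),
            sigma_g=Sg,
            sigma_e=Se,
            llf=-float(full.fun),
            llf_null=-float(null.fun),
            lrt=float(stat),
            pvalue=float(chi2.sf(stat, 1)),
            nobs=self.n,
            defined=defined,
        )

    def _rg_se(self, params: np.ndarray, eps: float) -> float:
        """Delta-method SE from a finite-difference Hessian of the REML surface."""
        k = len(params)
        H = np.zeros((k, k))
        f0 = self._neg_llf(params, False)
        for i in range(k):
            for j in range(i, k):
                pi, pj = np.eye(k)[i] * eps, np.eye(k)[j] * eps
                fpp = self._neg_llf(params + pi + pj, False)
                fpm = self._neg_llf(params + pi - pj, False)
                fmp = self._neg_llf(params - pi + pj, False)
                fmm = self._neg_llf(params - pi - pj, False)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
        def rg_of(p):
            Sg = _chol_from_params(p[:3])
            return Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1])
        grad = np.zeros(k)
        for i in range(k):
            step = np.eye(k)[i] * eps
            grad[i] = (rg_of(params + step) - rg_of(params - step)) / (2 * eps)
        try:
            cov = np.linalg.inv(H)
            var = float(grad @ cov @ grad)
            return float(np.sqrt(var)) if var > 0 else float("nan")
        except np.linalg.LinAlgError:
            return float("nan")


def genetic_correlation(y1, y2, covariates, grm) -> GeneticCorrResults:
    """Functional wrapper around :class:`GeneticCorrelationModel`."""
    return GeneticCorrelationModel(y1, y2, grm, covariates).fit()


def fdr_adjust(pvalues, method: str = "BH") -> np.ndarray:
    """Step-up FDR q-values (Benjamini-Hochberg by default, BY by flag)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown FDR method: {method}")
    return multipletests(p, method=key)[1]
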