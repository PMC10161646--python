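"""Mediation of QTL effects on phenotypes by molecular traits.

Given a trio (marker g, molecular mediator M, phenotype Y), two linear
models are fitted:

    mediator model   M = a g + covariates + e1
    outcome model    Y = c' g + b M + covariates + e2

The average causal mediation effect (ACME) is a*b, the average direct effect
(ADE) is c', the total effect a*b + c' (which equals the slope of Y ~ g for
linear models on complete data), and the proportion mediated is
a*b / (a*b + c'). Uncertainty comes from a nonparametric bootstrap over
samples (percentile intervals; the mediation p-value is the two-sided
bootstrap sign test on the ACME). In this linear no-interaction setting the
product-of-coefficients estimand coincides with the counterfactual one used
by quasi-Bayesian mediation software.

The simpler covariate-adjustment screen is also provided: the pQTL effect is
re-tested with the mediator as a covariate; a collapse of the association
indicates mediation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .heritability import fdr_adjust


def _ols(y: np.ndarray, X: np.ndarray):
    """Coefficients, their SEs and two-sided p-values for y = X b + e."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - rank
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    p = 2.0 * t_dist.sf(np.abs(tstat), df)
    return coef, se, p


def _complete_cases(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a if a.ndim == 1 else a).all(axis=-1) if a.ndim > 1 else np.isfinite(a)
    return mask


def adjusted_assoc_test(trait, marker_dosage, mediator, covariates=None):
    """(p_unadjusted, p_adjusted, flag) for the pQTL with/without the mediator.

    ``flag`` is "ok", "collinear" (mediator r^2 = 1 with the marker) or
    "degenerate" (mediator numerically identical to the trait).
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray(marker_dosage, dtype=float)
    m = np.asarray(mediator, dtype=float)
    C = None if covariates is None else np.asarray(covariates, dtype=float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    mask = np.isfinite(y) & np.isfinite(g) & np.isfinite(m)
    if C is not None:
        mask &= np.isfinite(C).all(axis=1)
    y, g, m = y[mask], g[mask], m[mask]
    C = None if C is None else C[mask]
    if y.size < 30:
        raise ValueError("need >= 30 complete cases")
    base = [np.ones_like(y), g] + ([] if C is None else [C])
    X0 = np.column_stack(base)
    _, _, p0 = _ols(y, X0)
    flag = "ok"
    r_gm = np.corrcoef(g, m)[0, 1] if g.std() > 0 and m.std() > 0 else 0.0
    if abs(r_gm) > 1 - 1e-10:
        return float(p0[1]), float("nan"), "collinear"
    if np.allclose(m, y):
        flag = "degenerate"
    X1 = np.column_stack(base[:2] + [m] + ([] if C is None else [C]))
    _, _, p1 = _ols(y, X1)
    return float(p0[1]), float(p1[1]), flag


@dataclass
class MediationResults:
    """Product-of-coefficients mediation estimates with bootstrap uncertainty."""

    acme: float
    ade: float
    total: float
    proportion_raw: float
    proportion: float            # clipped to [0, 1]
    ci_acme: tuple
    ci_proportion: tuple
    pvalue: float                # bootstrap two-sided p on the ACME
    p_unadjusted: float
    p_adjusted: float
    nobs: int
    n_boot: int
    defined: bool                # False when the total effect ~ 0

    def summary(self) -> str:
        lines = [
            "Mediation analysis (product of coefficients, bootstrap)",
            "-" * 55,
            f"n observations        {self.nobs:>10d}   bootstraps {self.n_boot}",
            f"ACME (mediated)       {self.acme:>10.4f}  CI [{self.ci_acme[0]:.4f}, {self.ci_acme[1]:.4f}]",
            f"ADE (direct)          {self.ade:>10.4f}",
            f"total effect          {self.total:>10.4f}",
            f"proportion mediated   {self.proportion:>10.4f}  (raw {self.proportion_raw:.4f})",
            f"mediation p           {self.pvalue:>10.3g}",
            f"pQTL p unadjusted     {self.p_unadjusted:>10.3g}   adjusted {self.p_adjusted:.3g}",
        ]
        if not self.defined:
            lines.append("warning: total effect ~ 0; proportion mediated undefined")
        return "\n".join(lines)


class MediationModel:
    """Linear mediation model for one (marker, mediator, trait) trio."""

    def __init__(self, trait, marker_dosage, mediator, covariates=None,
                 min_cases: int = 30):
        y = np.asarray(trait, dtype=float)
        g = np.asarray(marker_dosage, dtype=float)
        m = np.asarray(mediator, dtype=float)
        C = None if covariates is None else np.asarray(covariates, dtype=float)
        if C is not None and C.ndim == 1:
            C = C[:, None]
        mask = np.isfinite(y) & np.isfinite(g) & np.isfinite(m)
        if C is not None:
            mask &= np.isfinite(C).all(axis=1)
        if mask.sum() < min_cases:
            raise ValueError(f"need >= {min_cases} complete cases")
        self.y, self.g, self.m = y[mask], g[mask], m[mask]
        self.C = None if C is None else C[mask]

    def _effects(self, idx=None):
        y, g, m = self.y, self.g, self.m
        C = self.C
        if idx is not None:
            y, g, m = y[idx], g[idx], m[idx]
            C = None if C is None else C[idx]
        ones = np.ones_like(y)
        Xc = [] if C is None else [C]
        a = _ols(m, np.column_stack([ones, g] + Xc))[0][1]
        coef = _ols(y, np.column_stack([ones, g, m] + Xc))[0]
        c_prime, b = coef[1], coef[2]
        return a * b, c_prime

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> MediationResults:
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        acme, ade = self._effects()
        total = acme + ade
        scale = max(np.std(self.y), 1e-12)
        defined = abs(total) > 1e-8 * scale
        prop_raw = acme / total if defined else float("nan")
        rng = np.random.default_rng(seed)
        n = self.y.size
        boots = np.empty((n_boot, 2))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = self._effects(idx)
        b_acme = boots[:, 0]
        b_total = boots.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            b_prop = np.where(np.abs(b_total) > 1e-12, b_acme / b_total, np.nan)
        ci_acme = tuple(np.percentile(b_acme, [2.5, 97.5]))
        ci_prop = (
            tuple(np.nanpercentile(b_prop, [2.5, 97.5])) if defined else (np.nan, np.nan)
        )
        n_pos = int(np.sum(b_acme > 0))
        n_neg = int(np.sum(b_acme < 0))
        pval = 2.0 * (min(n_pos, n_neg) + 1) / (n_boot + 1)
        p0, p1, _ = adjusted_assoc_test(self.y, self.g, self.m, self.C)
        return MediationResults(
            acme=float(acme),
            ade=float(ade),
            total=float(total),
            proportion_raw=float(prop_raw),
            proportion=float(np.clip(prop_raw, 0.0, 1.0)) if defined else float("nan"),
            ci_acme=(float(ci_acme[0]), float(ci_acme[1])),
            ci_proportion=(float(ci_prop[0]), float(ci_prop[1])),
            pvalue=float(min(pval, 1.0)),
            p_unadjusted=p0,
            p_adjusted=p1,
            nobs=n,
            n_boot=n_boot,
            defined=defined,
        )


def mediate(marker_dosage, mediator, trait, covariates=None, n_boot=1000,
            seed=None) -> MediationResults:
    """Functional wrapper around :class:`MediationModel`."""
    return MediationModel(trait, marker_dosage, mediator, covariates).fit(
        n_boot=n_boot, seed=seed
    )


def build_trios(pqtl_calls: pd.DataFrame, molecular_calls: pd.DataFrame) -> pd.DataFrame:
    """Trios where the *same* marker is significant for a phenotype and a
    molecular trait.

    ``pqtl_calls`` needs columns (trait, marker); ``molecular_calls`` needs
    (trait, marker, kind) with kind in {splicing, expression}. Returns one
    row per (marker, mediator, trait, kind).
    """
    if pqtl_calls.empty or molecular_calls.empty:
        return pd.DataFrame(columns=["marker", "mediator_id", "mediator_kind", "trait"])
    merged = pqtl_calls[["trait", "marker"]].merge(
        molecular_calls[["trait", "marker", "kind"]].rename(
            columns={"trait": "mediator_id", "kind": "mediator_kind"}
        ),
        on="marker",
    )
    return (
        merged[["marker", "mediator_id", "mediator_kind", "trait"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )


def significant_mediators(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """BH-filter mediation results on the model-based mediation p-value."""
    if results.empty:
        out = results.copy()
        out["q"] = pd.Series(dtype=float)
        return out
    out = results.copy()
    out["q"] = fdr_adjust(out["p_mediation"].to_numpy())
    return out[out["q"] <= fdr].reset_index(drop=True)
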