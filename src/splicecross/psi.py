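"""PSI quantification, non-specific trait filters, and quantile normalisation.

PSI (percent spliced-in) for an event in one sample is the length-normalized
inclusion fraction

    PSI = (I / L_I) / (I / L_I + E / L_E)

with I, E the inclusion/exclusion junction read counts and L_I, L_E the
effective form lengths. A sample with I + E = 0 has no information about the
event and its PSI is missing, never zero.

The filters mirror a standard heritability-analysis pre-processing chain:

* evidence      — both isoforms seen with >= 2 reads in >= 2 samples;
* coverage      — >= 5 total junction reads in >= 50% of samples
                  (per-sample "estimable" mask reused downstream);
* variability   — on the 0-100 percent scale: mean absolute deviation > 1,
                  log2(variance) > 2, |skewness| < 1.1. The percent scale is
                  deliberate: on [0, 1] a mean absolute deviation above 1 is
                  impossible, so the stated thresholds are only satisfiable
                  on percent units;
* sex balance   — each sex contributes >= 20% of the estimable samples
                  (inclusive boundary).

The kept set is the intersection of the filters, so their order is
irrelevant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, skew

from .containers import JunctionCountTable


def compute_psi(inclusion, exclusion, inclusion_length, exclusion_length):
    """Length-normalized PSI; vectorized; NaN where I + E = 0.

    Accepts scalars or arrays (events x samples with per-event lengths).
    """
    inc = np.asarray(inclusion, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    li = np.asarray(inclusion_length, dtype=float)
    le = np.asarray(exclusion_length, dtype=float)
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("negative junction counts")
    if (li <= 0).any() or (le <= 0).any():
        raise ValueError("form lengths must be positive")
    if inc.ndim == 2 and li.ndim == 1:
        li = li[:, None]
        le = le[:, None]
    num = inc / li
    den = num + exc / le
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / den, np.nan)
    if psi.ndim == 0:
        return float(psi) if den > 0 else float("nan")
    return psi


def psi_matrix(counts: JunctionCountTable) -> pd.DataFrame:
    """PSI for every (event, sample); events x samples DataFrame in [0, 1]."""
    psi = compute_psi(
        counts.inclusion,
        counts.exclusion,
        counts.events["inclusion_length"].to_numpy(),
        counts.events["exclusion_length"].to_numpy(),
    )
    return pd.DataFrame(psi, index=counts.events.index, columns=counts.samples)


def event_evidence_filter(
    counts: JunctionCountTable, min_reads: int = 2, min_samples: int = 2
) -> pd.Series:
    """Both isoforms supported by >= min_reads reads in >= min_samples samples."""
    inc_ok = (counts.inclusion >= min_reads).sum(axis=1) >= min_samples
    exc_ok = (counts.exclusion >= min_reads).sum(axis=1) >= min_samples
    return pd.Series(inc_ok & exc_ok, index=counts.events.index, name="evidence")


def coverage_filter(
    counts: JunctionCountTable, min_total: int = 5, min_fraction: float = 0.5
) -> tuple[pd.Series, pd.DataFrame]:
    """Estimable = I + E >= min_total; keep event iff estimable fraction >= min_fraction.

    Returns (per-event keep verdict, events x samples estimable mask).
    """
    estimable = (counts.inclusion + counts.exclusion) >= min_total
    frac = estimable.mean(axis=1)
    keep = pd.Series(frac >= min_fraction, index=counts.events.index, name="coverage")
    mask = pd.DataFrame(estimable, index=counts.events.index, columns=counts.samples)
    return keep, mask


def variability_filter(
    psi_percent,
    mad_min: float = 1.0,
    log2var_min: float = 2.0,
    skew_max: float = 1.1,
    two_sided_skew: bool = True,
) -> bool:
    """Keep iff MAD > mad_min, log2(var) > log2var_min and skewness below skew_max.

    Operates on the 0-100 percent scale. MAD is the mean absolute deviation
    from the mean; variance is the unbiased sample variance; skewness is the
    adjusted Fisher-Pearson estimator, compared as |skew| < skew_max by
    default (set ``two_sided_skew=False`` for the literal one-sided reading).
    """
    x = np.asarray(psi_percent, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        warnings.warn("variability_filter: fewer than 3 non-missing values", stacklevel=2)
        return False
    mad = float(np.mean(np.abs(x - x.mean())))
    var = float(np.var(x, ddof=1))
    if mad <= mad_min or var <= 0 or np.log2(var) <= log2var_min:
        return False
    sk = float(skew(x, bias=False))
    sk_stat = abs(sk) if two_sided_skew else sk
    return sk_stat < skew_max


def sex_balance_filter(
    estimable: np.ndarray, sex: np.ndarray, min_fraction: float = 0.2
) -> bool:
    """Each sex comprises >= min_fraction of the estimable samples (inclusive)."""
    est = np.asarray(estimable, dtype=bool)
    sex = np.asarray(sex, dtype=object)
    n_est = est.sum()
    if n_est == 0:
        return False
    frac_f = np.sum(est & (sex == "F")) / n_est
    frac_m = np.sum(est & (sex == "M")) / n_est
    return bool(frac_f >= min_fraction and frac_m >= min_fraction)


def quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^{-1}((rank - 0.5) / m).

    Average ranks for ties; missing values stay missing; raises on constant
    input (the transform is undefined there).
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    obs = x[mask]
    if np.unique(obs).size < 2:
        raise ValueError("quantile_normalize requires >= 2 distinct non-missing values")
    ranks = rankdata(obs, method="average")
    out = np.full(x.shape, np.nan)
    out[mask] = norm.ppf((ranks - 0.5) / obs.size)
    return out


def filter_events(
    counts: JunctionCountTable,
    sex: np.ndarray,
    min_reads: int = 2,
    min_samples: int = 2,
    min_total: int = 5,
    min_cov_fraction: float = 0.5,
    mad_min: float = 1.0,
    log2var_min: float = 2.0,
    skew_max: float = 1.1,
    min_sex_fraction: float = 0.2,
) -> pd.DataFrame:
    """Apply the full filter chain; returns a per-event report.

    Columns: ``evidence``, ``coverage``, ``variability``, ``sex_balance``,
    ``kept`` (the conjunction). PSI values at non-estimable samples are
    treated as missing for the variability and sex-balance checks.
    """
    evidence = event_evidence_filter(counts, min_reads, min_samples)
    cov, estimable = coverage_filter(counts, min_total, min_cov_fraction)
    psi = psi_matrix(counts)
    psi_est = psi.where(estimable)
    variab = pd.Series(
        [
            variability_filter(
                100.0 * psi_est.iloc[i].to_numpy(), mad_min, log2var_min, skew_max
            )
            if np.isfinite(psi_est.iloc[i].to_numpy()).sum() >= 3
            else False
            for i in range(len(psi_est))
        ],
        index=psi.index,
        name="variability",
    )
    sexbal = pd.Series(
        [
            sex_balance_filter(estimable.iloc[i].to_numpy(), sex, min_sex_fraction)
            for i in range(len(estimable))
        ],
        index=psi.index,
        name="sex_balance",
    )
    report = pd.concat([evidence, cov, variab, sexbal], axis=1)
    report["kept"] = report.all(axis=1)
    return report
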