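"""Mixed-model QTL scans, permutation-based empirical FDR, forward model
selection and cis/trans classification.

The scan is the two-step ("fastGWA-style") mixed-model association test:
variance components are estimated once per trait under the no-marker model,
then every marker is tested by generalized least squares with that covariance
held fixed. Because the GRM eigendecomposition, the rotated genotypes and
the rotated design are shared across traits *and* across permutations, a
whole trait matrix is scanned with O(n x m) work per trait.

The empirical FDR follows the permutation scheme in which the sample labels
of the entire trait matrix are permuted jointly — one permutation applied to
every trait — preserving the correlation structure among molecular traits
while breaking their link to genotype. FDR(t) is the average permuted count
of significant tests at threshold t divided by the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import t as t_dist

from .containers import GenotypeMatrix
from .reml import ProjectedKernel, reml_profile, reml_profile_grid
from .heritability import _design

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = np.logspace(-10, -2, 33)


class _ScanEngine:
    """Shared rotated quantities for scanning many traits / permutations."""

    def __init__(self, genotypes: GenotypeMatrix, grm, covariates=None):
        G = grm.values if isinstance(grm, pd.DataFrame) else np.asarray(grm, float)
        n = genotypes.n_samples
        if G.shape != (n, n):
            raise ValueError("GRM not aligned to genotypes")
        self.genotypes = genotypes
        Z = genotypes.dosage.copy()
        col_mean = np.nanmean(Z, axis=0)
        nan_mask = np.isnan(Z)
        if nan_mask.any():
            Z[nan_mask] = np.broadcast_to(col_mean, Z.shape)[nan_mask]
        self.monomorphic = np.nanstd(Z, axis=0) == 0
        self.X = _design(n, covariates)
        self.n, self.p = self.X.shape
        d, U = eigh((G + G.T) / 2.0)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.Xs = U.T @ self.X
        self.Zs = U.T @ Z
        self.kernel = ProjectedKernel.build(G, self.X)

    def ratios(self, Y: np.ndarray, method: str = "exact") -> np.ndarray:
        """Per-trait REML variance ratio under the no-marker model.

        ``Y`` is traits x samples. ``method="grid"`` uses the vectorized
        grid REML (ample for permutation scans), ``"exact"`` polishes each
        trait with Brent search.
        """
        Omega = self.kernel.rotate(Y.T)
        if method == "grid":
            return reml_profile_grid(Omega, self.kernel.theta)
        lams = np.empty(Y.shape[0])
        for i in range(Y.shape[0]):
            lams[i], _, _, _ = reml_profile(Omega[:, i], self.kernel.theta)
        return lams

    def scan_trait(self, y: np.ndarray, lam: float):
        """GLS marker stats for one trait at fixed variance ratio."""
        ys = self.U.T @ y
        sw = 1.0 / np.sqrt(lam * self.d + 1.0)
        yw = ys * sw
        Xw = self.Xs * sw[:, None]
        Zw = self.Zs * sw[:, None]
        XtX = Xw.T @ Xw
        coefy = np.linalg.solve(XtX, Xw.T @ yw)
        ry = yw - Xw @ coefy
        coefZ = np.linalg.solve(XtX, Xw.T @ Zw)
        RZ = Zw - Xw @ coefZ
        czz = np.einsum("ij,ij->j", RZ, RZ)
        ok = ~self.monomorphic & (czz > 1e-12)
        beta = np.full(czz.shape, np.nan)
        se = np.full(czz.shape, np.nan)
        pv = np.full(czz.shape, np.nan)
        df = self.n - self.p - 1
        cyz = RZ.T @ ry
        ryy = float(ry @ ry)
        b = cyz[ok] / czz[ok]
        rss = np.maximum(ryy - b**2 * czz[ok], 0.0)
        sigma2 = rss / df
        s = np.sqrt(sigma2 / czz[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = b / s
        beta[ok], se[ok] = b, s
        pv[ok] = 2.0 * t_dist.sf(np.abs(tstat), df)
        return beta, se, pv

    def scan_matrix(self, Y: np.ndarray, lams: np.ndarray):
        """Scan a trait matrix, batching traits that share a variance ratio.

        Ratios from the grid REML take few distinct values, so traits are
        grouped by ratio and each group is scanned with matrix products
        instead of a per-trait loop; identical results, much faster for the
        permutation null.
        """
        T, m = Y.shape[0], self.Zs.shape[1]
        betas = np.empty((T, m))
        ses = np.empty((T, m))
        pvs = np.empty((T, m))
        Ys = Y @ self.U  # T x n, rotated
        df = self.n - self.p - 1
        ok = ~self.monomorphic
        for lam in np.unique(lams):
            rows = np.where(lams == lam)[0]
            sw = 1.0 / np.sqrt(lam * self.d + 1.0)
            Xw = self.Xs * sw[:, None]
            Zw = self.Zs * sw[:, None]
            XtX = Xw.T @ Xw
            RZ = Zw - Xw @ np.linalg.solve(XtX, Xw.T @ Zw)
            czz = np.einsum("ij,ij->j", RZ, RZ)
            good = ok & (czz > 1e-12)
            Yw = Ys[rows] * sw
            # residualize each (row) trait on the weighted design
            RY = Yw - (Yw @ Xw) @ np.linalg.solve(XtX, Xw.T)
            cyz = RY @ RZ
            ryy = np.einsum("ij,ij->i", RY, RY)
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(good, cyz / czz, np.nan)
                rss = np.maximum(ryy[:, None] - b**2 * czz, 0.0)
                s = np.sqrt(rss / df / czz)
                tstat = b / s
            p = np.full_like(b, np.nan)
            fin = np.isfinite(tstat)
            p[fin] = 2.0 * t_dist.sf(np.abs(tstat[fin]), df)
            b[:, ~good] = np.nan
            s[:, ~good] = np.nan
            p[:, ~good] = np.nan
            betas[rows], ses[rows], pvs[rows] = b, s, p
        return betas, ses, pvs


@dataclass
class ScanResults:
    """Per-marker association statistics for one or more traits."""

    traits: pd.Index
    markers: pd.DataFrame
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    ratios: np.ndarray

    def table(self) -> pd.DataFrame:
        """Long-format (trait, marker, chrom, pos, beta, se, p)."""
        rows = []
        for i, t in enumerate(self.traits):
            df = pd.DataFrame(
                {
                    "trait": t,
                    "marker": self.markers.index,
                    "chrom": self.markers["chrom"].to_numpy(),
                    "pos": self.markers["pos"].to_numpy(),
                    "beta": self.beta[i],
                    "se": self.se[i],
                    "p": self.pvalues[i],
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def pvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.traits, columns=self.markers.index)

    def significant(self, threshold: float) -> pd.DataFrame:
        tab = self.table()
        return tab[tab["p"] <= threshold].reset_index(drop=True)


class AssociationScan:
    """Mixed-model single-marker scan; ``fit()`` returns :class:`ScanResults`.

    Parameters
    ----------
    traits : Series or DataFrame
        One trait (indexed by sample) or a traits x samples matrix. Missing
        molecular-trait values are mean-imputed (zero on the
        quantile-normalized scale) so the rotation can be shared.
    genotypes : GenotypeMatrix
    grm : DataFrame or ndarray aligned to the genotype samples
    covariates : array-like, optional (intercept always included)
    """

    def __init__(self, traits, genotypes: GenotypeMatrix, grm, covariates=None):
        if isinstance(traits, pd.Series):
            traits = traits.to_frame().T
        self.trait_ids = traits.index
        Y = traits.reindex(columns=genotypes.samples).to_numpy(dtype=float)
        means = np.nanmean(Y, axis=1)
        nan_mask = np.isnan(Y)
        if nan_mask.any():
            Y[nan_mask] = np.broadcast_to(means[:, None], Y.shape)[nan_mask]
        self.Y = Y
        self.engine = _ScanEngine(genotypes, grm, covariates)

    def fit(self, vc_method: str = "exact") -> ScanResults:
        lams = self.engine.ratios(self.Y, method=vc_method)
        beta, se, pv = self.engine.scan_matrix(self.Y, lams)
        return ScanResults(
            traits=self.trait_ids,
            markers=self.engine.genotypes.markers,
            beta=beta,
            se=se,
            pvalues=pv,
            ratios=lams,
        )


def mlm_scan(trait, genotypes, grm, covariates=None, vc_method="exact") -> ScanResults:
    """Functional wrapper: scan one trait or a trait matrix."""
    return AssociationScan(trait, genotypes, grm, covariates).fit(vc_method)


# ---------------------------------------------------------------------------
# Permutation-based empirical FDR
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Observed vs permuted significant-test counts on a p-value grid."""

    threshold_grid: np.ndarray
    observed_counts: np.ndarray
    perm_counts: np.ndarray      # n_perm x n_grid
    n_perm: int
    seed: int | None
    fdr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        mean_perm = self.perm_counts.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(self.observed_counts > 0,
                           mean_perm / np.maximum(self.observed_counts, 1), np.nan)
        self.fdr = np.minimum(fdr, 1.0)

    def threshold_at(self, target_fdr: float):
        """Largest grid threshold with estimated FDR <= target; None if none."""
        ok = np.where(np.isfinite(self.fdr) & (self.fdr <= target_fdr)
                      & (self.observed_counts > 0))[0]
        if ok.size == 0:
            return None
        return float(self.threshold_grid[ok.max()])


def _grid_counts(pv: np.ndarray, grid: np.ndarray) -> np.ndarray:
    flat = np.sort(pv[np.isfinite(pv)].ravel())
    return np.searchsorted(flat, grid, side="right")


def permutation_fdr(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    grm,
    covariates=None,
    n_perm: int = 200,
    threshold_grid=None,
    target_fdr: float = 0.01,
    seed: int | None = None,
    vc_method: str = "grid",
) -> tuple[PermutationNull, float | None, ScanResults]:
    """Empirical FDR by joint sample-label permutation of the trait matrix.

    Genotypes, GRM and covariates stay tied to sample identity; only the
    trait matrix rows are re-labelled, the same permutation for every trait.
    FDR(t) = mean permuted count of p <= t over permutations divided by the
    observed count. Returns (null, threshold achieving ``target_fdr`` or
    None, observed ScanResults).
    """
    if len(traits) < 2:
        raise ValueError("permutation FDR needs >= 2 traits to preserve correlation")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = np.asarray(DEFAULT_THRESHOLD_GRID if threshold_grid is None else threshold_grid)
    rng = np.random.default_rng(seed)
    scan = AssociationScan(traits, genotypes, grm, covariates)
    observed = scan.fit(vc_method=vc_method)
    obs_counts = _grid_counts(observed.pvalues, grid)
    engine, Y = scan.engine, scan.Y
    perm_counts = np.empty((n_perm, grid.size), dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(Y.shape[1])
        Yp = Y[:, perm]
        lams = engine.ratios(Yp, method=vc_method)
        _, _, pv = engine.scan_matrix(Yp, lams)
        perm_counts[b] = _grid_counts(pv, grid)
    null = PermutationNull(
        threshold_grid=grid,
        observed_counts=obs_counts,
        perm_counts=perm_counts,
        n_perm=n_perm,
        seed=seed,
    )
    if obs_counts.max() == 0:
        logger.info("permutation_fdr: nothing significant at any grid threshold")
        return null, None, observed
    return null, null.threshold_at(target_fdr), observed


# ---------------------------------------------------------------------------
# Forward model selection
# ---------------------------------------------------------------------------

def forward_select(
    trait,
    candidate_markers,
    genotypes: GenotypeMatrix,
    grm,
    covariates=None,
    p_enter: float = 1e-4,
    lam: float | None = None,
) -> pd.DataFrame:
    """Greedy conditional GLS selection among scan-significant markers.

    At each step the candidate with the smallest conditional p-value (in a
    model containing the already-retained markers) is added while that p is
    <= ``p_enter``. Ties break on (p, genomic order). Candidates collinear
    with the retained set are skipped and logged. Returns a DataFrame of
    retained markers with their conditional p at entry.
    """
    cand = [m for m in candidate_markers if m in genotypes.markers.index]
    order = {m: genotypes.markers.index.get_loc(m) for m in cand}
    cand = sorted(cand, key=order.get)
    if not cand:
        return pd.DataFrame(columns=["marker", "p_conditional"])

    engine = _ScanEngine(genotypes, grm, covariates)
    y = (trait.reindex(genotypes.samples) if isinstance(trait, pd.Series)
         else pd.Series(trait, index=genotypes.samples)).to_numpy(dtype=float)
    y = np.where(np.isnan(y), np.nanmean(y), y)
    if lam is None:
        lam = float(engine.ratios(y[None, :], method="exact")[0])
    sw = 1.0 / np.sqrt(lam * engine.d + 1.0)
    yw = (engine.U.T @ y) * sw
    Xw = engine.Xs * sw[:, None]
    cols = {m: engine.Zs[:, order[m]] * sw for m in cand}

    retained: list[tuple[str, float]] = []
    design = Xw
    remaining = list(cand)
    n = engine.n
    while remaining:
        dfree = n - design.shape[1] - 1
        if dfree < 1:
            break
        coef_y, _, _, _ = np.linalg.lstsq(design, yw, rcond=None)
        ry = yw - design @ coef_y
        stats = []
        drop = []
        for m in remaining:
            z = cols[m]
            coef_z, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
            rz = z - design @ coef_z
            czz = float(rz @ rz)
            if czz <= 1e-10 * float(z @ z):
                logger.info("forward_select: %s collinear with retained set, skipped", m)
                drop.append(m)
                continue
            b = float(rz @ ry) / czz
            rss = max(float(ry @ ry) - b**2 * czz, 0.0)
            se = np.sqrt(rss / dfree / czz)
            p = 2.0 * t_dist.sf(abs(b / se), dfree) if se > 0 else 0.0
            stats.append((p, order[m], m))
        for m in drop:
            remaining.remove(m)
        if not stats:
            break
        stats.sort()
        p_best, _, m_best = stats[0]
        if p_best > p_enter:
            break
        retained.append((m_best, p_best))
        design = np.column_stack([design, cols[m_best]])
        remaining.remove(m_best)
    return pd.DataFrame(retained, columns=["marker", "p_conditional"])


# ---------------------------------------------------------------------------
# cis / trans classification and summaries
# ---------------------------------------------------------------------------

def cis_label(marker_chrom, marker_pos, gene_chrom, gene_start, gene_end,
              window: int = 1_000_000) -> str:
    """"cis" iff same chromosome and within ``window`` of the gene boundaries
    (inclusive at exactly the window edge), else "trans"."""
    if str(marker_chrom) == str(gene_chrom) and (
        gene_start - window <= marker_pos <= gene_end + window
    ):
        return "cis"
    return "trans"


def classify_cis_trans(
    calls: pd.DataFrame,
    marker_map: pd.DataFrame,
    trait_coords: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Label each (trait, marker) call cis or trans.

    ``trait_coords`` is indexed by trait id with columns chrom/start/end (for
    splice events, the parent gene's boundaries). Traits without coordinates
    get a missing label.
    """
    out = calls.copy()
    labels = []
    for _, row in calls.iterrows():
        t, m = row["trait"], row["marker"]
        if t not in trait_coords.index or m not in marker_map.index:
            labels.append(pd.NA)
            continue
        mk = marker_map.loc[m]
        tc = trait_coords.loc[t]
        labels.append(cis_label(mk["chrom"], mk["pos"], tc["chrom"],
                                tc["start"], tc["end"], window))
    out["label"] = labels
    return out


def summarize_qtl(calls: pd.DataFrame) -> pd.Series:
    """Tabulate traits with >= 1 QTL into cis-only / trans-only / both.

    ``calls`` needs columns trait and label. Returns the Total/cis/trans/both
    schema (counts of traits, plus total retained markers).
    """
    if calls.empty:
        return pd.Series({"traits_total": 0, "cis_only": 0, "trans_only": 0,
                          "both": 0, "markers_total": 0})
    per = calls.dropna(subset=["label"]).groupby("trait")["label"].agg(set)
    cis_only = int(sum(s == {"cis"} for s in per))
    trans_only = int(sum(s == {"trans"} for s in per))
    both = int(sum(s == {"cis", "trans"} for s in per))
    return pd.Series({
        "traits_total": int(calls["trait"].nunique()),
        "cis_only": cis_only,
        "trans_only": trans_only,
        "both": both,
        "markers_total": int(len(calls)),
    })
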