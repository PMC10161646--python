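"""GRM construction, REML heritability, boundary LRT, genetic correlation,
and BH FDR — each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import splicecross as sc
from splicecross.reml import ProjectedKernel


def _geno(dosage, sex=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, m + 1) * 1000},
        index=pd.Index([f"M{j}" for j in range(m)], name="marker"),
    )
    return sc.GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        sex=np.array(sex if sex is not None else ["M", "F"] * (n // 2 + 1), dtype=object)[:n],
        markers=markers,
        dosage=dosage,
    )


class TestGrm:
    def test_hand_vanraden(self):
        """3 samples x 2 markers, computed by hand matrix algebra."""
        g = _geno([[0, 2], [1, 1], [2, 0]])
        G = sc.compute_grm(g, maf_min=0.0).values
        # p = (0.5, 0.5); Z = [[-1,1],[0,0],[1,-1]]; denom = 2*(0.25+0.25) = 1
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(G, expected, atol=1e-12)

    def test_duplicate_samples_share_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(5, 50)).astype(float)
        X[1] = X[0]
        G = sc.compute_grm(_geno(X), maf_min=0.0).values
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)
        assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-12)

    def test_hwe_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 5000)
        X = rng.binomial(2, p, size=(200, 5000)).astype(float)
        G = sc.compute_grm(_geno(X)).values
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)

    def test_missing_mean_imputed(self):
        X = np.array([[0, 2], [1, 1], [2, 0], [np.nan, 1]])
        G = sc.compute_grm(_geno(X), maf_min=0.0)
        assert np.isfinite(G.values).all()

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            sc.compute_grm(_geno(np.zeros((4, 3))))


def _sim_trait(G, h2, rng, X=None):
    n = G.shape[0]
    d, U = np.linalg.eigh(G)
    L = U * np.sqrt(np.clip(d, 0, None))
    y = np.sqrt(h2) * (L @ rng.standard_normal(n)) + np.sqrt(1 - h2) * rng.standard_normal(n)
    if X is not None:
        y = y + X @ np.array([1.0, 0.5])[: X.shape[1]]
    return y


class TestHeritabilityModel:
    def test_null_trait_h2_near_zero(self, grm, sex_cov):
        rng = np.random.default_rng(2)
        h2s, lrts = [], []
        for _ in range(20):
            y = rng.standard_normal(grm.shape[0])
            res = sc.HeritabilityModel(y, grm, sex_cov).fit()
            h2s.append(res.h2)
            lrts.append(res.lrt)
        assert np.median(h2s) < 0.1
        assert np.median(lrts) < 1.0

    def test_profile_optimum_beats_grid_oracle(self):
        """Brent optimum >= a dense 200-point grid search, 20 small instances."""
        rng = np.random.default_rng(3)
        grid = np.concatenate([[0.0], np.logspace(-6, 6, 200)])
        for _ in range(20):
            n = rng.integers(20, 51)
            A = rng.standard_normal((n, n))
            G = A @ A.T / n
            y = _sim_trait(G, rng.uniform(0, 0.9), rng)
            model = sc.HeritabilityModel(y, G)
            res = model.fit()
            grid_best = max(model.loglike(lam) for lam in grid)
            assert res.llf >= grid_best - 1e-6

    def test_affine_invariance(self, grm, sex_cov):
        rng = np.random.default_rng(4)
        y = _sim_trait(grm.values, 0.4, rng)
        r1 = sc.HeritabilityModel(y, grm, sex_cov).fit()
        r2 = sc.HeritabilityModel(3.0 * y + 7.0, grm, sex_cov).fit()
        assert r2.h2 == pytest.approx(r1.h2, abs=1e-6)
        assert r2.lrt == pytest.approx(r1.lrt, abs=1e-5)

    def test_identity_grm_flagged(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(60)
        res = sc.HeritabilityModel(y, np.eye(60)).fit()
        assert not res.identifiable
        assert np.isnan(res.h2)

    def test_missing_dropped_infinite_rejected(self, grm):
        y = np.full(grm.shape[0], 1.0)
        y[:70] = np.random.default_rng(6).standard_normal(70)
        y[5] = np.nan
        res = sc.HeritabilityModel(y, grm).fit()
        assert res.nobs == grm.shape[0] - 1
        y[6] = np.inf
        with pytest.raises(ValueError):
            sc.HeritabilityModel(y, grm)

    def test_summary_mentions_h2(self, grm):
        y = np.random.default_rng(7).standard_normal(grm.shape[0])
        assert "h^2" in sc.HeritabilityModel(y, grm).fit().summary()


class TestBoundaryLrt:
    def test_zero_statistic(self):
        stat, p = sc.heritability_lrt(10.0, 10.0)
        assert stat == 0.0
        assert p == 0.5

    def test_closed_form_mixture(self):
        stat, p = sc.heritability_lrt(10.0 + 3.841 / 2, 10.0)
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(0.5 * chi2.sf(3.841, 1), rel=1e-10)
        assert p == pytest.approx(0.025, abs=1e-3)

    def test_plain_chi2_option(self):
        _, p = sc.heritability_lrt(12.0, 10.0, boundary_mixture=False)
        assert p == pytest.approx(chi2.sf(4.0, 1), rel=1e-12)


class TestGeneticCorrelation:
    def test_self_correlation_is_one(self, grm, sex_cov):
        rng = np.random.default_rng(8)
        y = _sim_trait(grm.values, 0.6, rng)
        res = sc.GeneticCorrelationModel(y, y + 1e-6 * rng.standard_normal(len(y)),
                                         grm, sex_cov).fit()
        assert res.r_g == pytest.approx(1.0, abs=0.02)
        assert res.r_e == pytest.approx(1.0, abs=0.05)

    def test_shared_genetics_detected(self, grm_large):
        """Traits built on the same genetic values: high r_G, significant LRT."""
        rng = np.random.default_rng(9)
        G = grm_large.values
        d, U = np.linalg.eigh(G)
        gvals = (U * np.sqrt(np.clip(d, 0, None))) @ rng.standard_normal(G.shape[0])
        y1 = np.sqrt(0.5) * gvals + np.sqrt(0.5) * rng.standard_normal(G.shape[0])
        y2 = np.sqrt(0.5) * gvals + np.sqrt(0.5) * rng.standard_normal(G.shape[0])
        res = sc.GeneticCorrelationModel(y1, y2, grm_large).fit()
        assert res.r_g > 0.6
        assert res.pvalue < 0.01

    def test_independent_genetics_near_zero(self, grm_large):
        rng = np.random.default_rng(10)
        G = grm_large.values
        y1 = _sim_trait(G, 0.5, rng)
        y2 = _sim_trait(G, 0.5, rng)
        res = sc.GeneticCorrelationModel(y1, y2, grm_large).fit()
        assert abs(res.r_g) < 0.35

    def test_min_overlap_enforced(self, grm):
        y = np.full(grm.shape[0], np.nan)
        y[:10] = 1.0
        with pytest.raises(ValueError):
            sc.GeneticCorrelationModel(y, y, grm)


def _bh_oracle(p):
    """Textbook step-up BH, written independently of the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestFdrAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            sc.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_and_degenerate(self):
        assert sc.fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(sc.fdr_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = rng.uniform(size=40)
            np.testing.assert_allclose(sc.fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sc.fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            sc.fdr_adjust([0.5], method="bonferroni-ish")


def test_projected_kernel_dimensions(grm):
    X = np.column_stack([np.ones(grm.shape[0]), np.arange(grm.shape[0])])
    k = ProjectedKernel.build(grm.values, X)
    assert k.basis.shape == (grm.shape[0], grm.shape[0] - 2)
    assert k.theta.shape == (grm.shape[0] - 2,)
    # basis orthonormal and orthogonal to X
    np.testing.assert_allclose(k.basis.T @ k.basis, np.eye(grm.shape[0] - 2), atol=1e-8)
    np.testing.assert_allclose(k.basis.T @ X, 0.0, atol=1e-8)
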