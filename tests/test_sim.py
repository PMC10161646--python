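"""Synthetic F2-cross generator: founders, meiosis, counts, expression,
phenotypes — all against closed-form or regression oracles."""

import numpy as np
import pandas as pd
import pytest

import splicecross as sc
from splicecross.sim import ConfigurationError


class TestFounders:
    def test_no_divergence_centers_on_zero(self):
        spec = sc.PedigreeSpec(n_founders_a=100, n_founders_b=100)
        genome = sc.GenomeSpec(n_markers=1000)
        g = sc.simulate_founders(spec, genome, fst=0.0, seed=1)
        in_a = [s.startswith("FA") for s in g.samples]
        pa = g.dosage[in_a].mean(axis=0) / 2
        pb = g.dosage[[not x for x in in_a]].mean(axis=0) / 2
        assert abs(np.mean(pa - pb)) < 0.01

    def test_balding_nichols_divergence_variance(self):
        """Mean squared frequency difference matches the model's closed form.

        Var(p_A - p_B | p) = 2 F p(1-p); with ancestral p ~ U(0.1, 0.9),
        E[p(1-p)] = 0.25 - 0.64/12. Finite founder panels add binomial
        sampling variance p(1-p)/(2 n) per group, included in the oracle.
        """
        fst, na, nb = 0.3, 200, 200
        spec = sc.PedigreeSpec(n_founders_a=na, n_founders_b=nb)
        genome = sc.GenomeSpec(n_markers=2000)
        g = sc.simulate_founders(spec, genome, fst=fst, seed=2)
        in_a = np.array([s.startswith("FA") for s in g.samples])
        pa = g.dosage[in_a].mean(axis=0) / 2
        pb = g.dosage[~in_a].mean(axis=0) / 2
        observed = np.mean((pa - pb) ** 2)
        e_pq = 0.25 - 0.8**2 / 12
        expected = e_pq * (2 * fst + 1 / (2 * na) + 1 / (2 * nb))
        assert observed == pytest.approx(expected, rel=0.15)

    def test_seed_determinism(self):
        spec, genome = sc.PedigreeSpec(), sc.GenomeSpec(n_markers=200)
        a = sc.simulate_founders(spec, genome, fst=0.2, seed=7)
        b = sc.simulate_founders(spec, genome, fst=0.2, seed=7)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_invalid_spec(self):
        with pytest.raises(ConfigurationError):
            sc.PedigreeSpec(n_f2=1)
        with pytest.raises(ConfigurationError):
            sc.simulate_founders(sc.PedigreeSpec(), sc.GenomeSpec(), fst=1.0)
        with pytest.raises(ConfigurationError):
            sc.GenomeSpec(chromosomes=[("1", 0)])


def _fixed_line_founders(genome):
    """Breed A fixed for the alternate allele, breed B for the reference."""
    markers = genome.marker_map()
    m = len(markers)
    na, nb = 4, 4
    hap = np.concatenate(
        [np.ones((na, 2, m), dtype=np.int8), np.zeros((nb, 2, m), dtype=np.int8)]
    )
    return sc.GenotypeMatrix(
        samples=[f"FA{i:02d}" for i in range(na)] + [f"FB{i:02d}" for i in range(nb)],
        sex=np.array(["M", "F"] * 4, dtype=object),
        markers=markers,
        dosage=hap.sum(axis=1).astype(float),
        haplotypes=hap,
    )


class TestF2:
    def test_no_recombination_keeps_haplotypes_intact(self):
        genome = sc.GenomeSpec(n_markers=200, recombination_rate=0.0)
        spec = sc.PedigreeSpec(n_f2=20)
        founders = sc.simulate_founders(spec, genome, fst=0.3, seed=3)
        f2, _ = sc.simulate_f2(founders, spec, genome, seed=4)
        founder_haps = founders.haplotypes.reshape(-1, founders.n_markers)
        for name, _ in genome.chromosomes:
            cols = np.where(founders.markers["chrom"] == name)[0]
            pool = {h[cols].tobytes() for h in founder_haps}
            for i in range(f2.n_samples):
                for k in (0, 1):
                    assert f2.haplotypes[i, k, cols].tobytes() in pool

    def test_fixed_lines_give_uniformly_heterozygous_f1(self):
        genome = sc.GenomeSpec(n_markers=100)
        spec = sc.PedigreeSpec(n_founders_a=4, n_founders_b=4, n_f1=10, n_f2=5)
        founders = _fixed_line_founders(genome)
        _, _, f1 = sc.simulate_f2(founders, spec, genome, seed=5, return_f1=True)
        assert (f1.dosage == 1.0).all()

    def test_ld_decays_with_distance(self, f2_large):
        """Adjacent-marker r^2 in F2 exceeds long-range r^2 (1 cM vs 50 cM)."""
        g = f2_large
        poly = g.dosage.std(axis=0) > 0
        chrom1 = np.where((g.markers["chrom"] == "1").to_numpy() & poly)[0]
        pos = g.markers["pos"].to_numpy()[chrom1] / 1e6  # Mb = cM at 1 cM/Mb
        X = g.dosage[:, chrom1]
        corr = np.corrcoef(X.T) ** 2
        d = np.abs(pos[:, None] - pos[None, :])
        near = corr[(d > 0) & (d <= 2.0)]
        far = corr[d >= 45.0]
        assert near.mean() > 2 * far.mean()

    def test_pedigree_structure(self, f2_cohort):
        ped = f2_cohort["pedigree"]
        assert (ped.loc[ped["generation"] == "F2", "sire"].str.startswith("F1")).all()
        assert len(ped[ped["generation"] == "F2"]) == 143


class TestJunctionCounts:
    def _truth_single(self, markers, mu=0.0, h2=0.0, li=100, le=100):
        events = pd.DataFrame(
            {
                "gene_id": ["G1"], "event_class": ["SE"], "chrom": ["1"],
                "start": [100], "end": [200],
                "inclusion_length": [li], "exclusion_length": [le],
                "mu": [mu], "h2": [h2],
                "sqtl_marker": pd.array([pd.NA], dtype="string"), "beta": [0.0],
            },
            index=pd.Index(["E1"], name="event_id"),
        )
        genes = pd.DataFrame(
            columns=["chrom", "start", "end", "mu", "h2", "eqtl_marker", "beta"]
        )
        traits = pd.DataFrame(
            columns=["pqtl_marker", "mediator_id", "mediator_kind",
                     "proportion_mediated", "total_effect", "sex_effect", "resid_sd"]
        )
        return sc.SimTruth(events=events, genes=genes, traits=traits)

    def test_symmetric_null_psi_half(self, f2):
        truth = self._truth_single(f2.markers, mu=0.0, h2=0.0)
        ct = sc.simulate_junction_counts(f2, truth, coverage_mean=200, seed=8)
        psi = sc.psi_matrix(ct)
        # latent logit ~ N(0,1) is symmetric around 0.5 after the sigmoid
        assert np.nanmean(psi.values) == pytest.approx(0.5, abs=0.05)

    def test_length_weighting_inverts_to_psi(self):
        """psi=0.6, L_I=2, L_E=1: inclusion fraction 0.75, and the PSI
        estimator applied to the expected counts returns 0.6."""
        psi, li, le = 0.6, 2, 1
        p_inc = psi * li / (psi * li + (1 - psi) * le)
        assert p_inc == pytest.approx(0.75)
        total = 1_000_000
        assert sc.compute_psi(total * p_inc, total * (1 - p_inc), li, le) == pytest.approx(0.6)

    def test_zero_coverage_is_missing(self, f2):
        truth = self._truth_single(f2.markers)
        ct = sc.simulate_junction_counts(f2, truth, coverage_mean=0.05, seed=9)
        psi = sc.psi_matrix(ct)
        zero = (ct.inclusion + ct.exclusion) == 0
        assert zero.any()
        assert np.isnan(psi.values[zero]).all()

    def test_coverage_must_be_positive(self, f2):
        with pytest.raises(ConfigurationError):
            sc.simulate_junction_counts(f2, self._truth_single(f2.markers), 0.0)


class TestExpression:
    def _truth(self, marker=None, h2=0.01, beta=0.0, n_genes=1):
        genes = pd.DataFrame(
            {
                "chrom": ["1"] * n_genes, "start": [100] * n_genes,
                "end": [200] * n_genes, "mu": [1.0] * n_genes,
                "h2": [h2] * n_genes,
                "eqtl_marker": pd.array([marker] * n_genes, dtype="string"),
                "beta": [beta] * n_genes,
            },
            index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene_id"),
        )
        events = pd.DataFrame(
            columns=["gene_id", "event_class", "chrom", "start", "end",
                     "inclusion_length", "exclusion_length", "mu", "h2",
                     "sqtl_marker", "beta"]
        )
        traits = pd.DataFrame(
            columns=["pqtl_marker", "mediator_id", "mediator_kind",
                     "proportion_mediated", "total_effect", "sex_effect", "resid_sd"]
        )
        return sc.SimTruth(events=events, genes=genes, traits=traits)

    def test_pure_noise_gene_uncorrelated_with_markers(self, f2):
        truth = self._truth(h2=0.0)
        expr = sc.simulate_expression(f2, truth, seed=10)
        y = np.log(expr.iloc[0].to_numpy())
        cors = [
            np.corrcoef(y, f2.dosage[:, j])[0, 1]
            for j in range(0, f2.n_markers, 10)
            if f2.dosage[:, j].std() > 0
        ]
        assert abs(np.mean(cors)) < 0.05

    def test_eqtl_variance_fraction(self, f2_large):
        """Effect sized for 25% of log-variance yields regression R^2 ~ 0.25."""
        marker = f2_large.markers.index[50]
        g = f2_large.dosage[:, 50]
        # residual latent variance is 1 (h2 ~ 0): var(beta g) = 1/3 -> R2 = 0.25
        beta = np.sqrt(1.0 / (3.0 * g.var()))
        truth = self._truth(marker=marker, h2=1e-6, beta=beta)
        expr = sc.simulate_expression(f2_large, truth, seed=11)
        y = np.log(expr.iloc[0].to_numpy())
        r2 = np.corrcoef(y, g)[0, 1] ** 2
        assert r2 == pytest.approx(0.25, abs=0.07)

    def test_strictly_positive(self, f2):
        expr = sc.simulate_expression(f2, self._truth(h2=0.3, n_genes=5), seed=12)
        assert (expr.to_numpy() > 0).all()


class TestPhenotypes:
    def _setup(self, geno, prop, sex_effect=0.5, seed=13):
        marker = geno.markers.index[100]
        rng = np.random.default_rng(99)
        g = geno.dosage[:, 100]
        med = pd.DataFrame(
            {"row": 0.8 * g + rng.normal(0, 0.5, geno.n_samples)}
        ).T
        med.index = ["MED1"]
        med.columns = geno.samples
        traits = pd.DataFrame(
            {
                "pqtl_marker": [marker], "mediator_id": ["MED1"],
                "mediator_kind": ["splicing"], "proportion_mediated": [prop],
                "total_effect": [1.0], "sex_effect": [sex_effect], "resid_sd": [1.0],
            },
            index=pd.Index(["T1"], name="trait_id"),
        )
        truth = sc.SimTruth(
            events=pd.DataFrame(), genes=pd.DataFrame(), traits=traits
        )
        ph = sc.simulate_phenotypes(geno, med, truth, seed=seed)
        return g, med.loc["MED1"].to_numpy(), ph["T1"].to_numpy(), ph

    @staticmethod
    def _marker_slope(y, g, m=None):
        X = np.column_stack([np.ones_like(g), g] + ([m] if m is not None else []))
        return np.linalg.lstsq(X, y, rcond=None)[0][1]

    def test_full_mediation_kills_adjusted_slope(self, f2_large):
        g, m, y, _ = self._setup(f2_large, prop=1.0)
        raw = self._marker_slope(y, g)
        adj = self._marker_slope(y, g, m)
        assert abs(raw) > 0.5
        assert abs(adj) < 0.2

    def test_zero_mediation_slope_unchanged(self, f2_large):
        g, m, y, _ = self._setup(f2_large, prop=0.0)
        raw = self._marker_slope(y, g)
        adj = self._marker_slope(y, g, m)
        assert raw == pytest.approx(1.0, abs=0.2)
        assert adj == pytest.approx(raw, abs=0.25)

    def test_sex_effect_recovered(self, f2_large):
        _, _, y, ph = self._setup(f2_large, prop=0.0, sex_effect=2.0)
        male = (ph["sex"] == "M").to_numpy()
        assert y[male].mean() - y[~male].mean() == pytest.approx(2.0, abs=0.35)

    def test_zero_variance_mediator_rejected(self, f2):
        med = pd.DataFrame(
            np.full((1, f2.n_samples), 0.7), index=["MED1"], columns=f2.samples
        )
        traits = pd.DataFrame(
            {
                "pqtl_marker": [f2.markers.index[0]], "mediator_id": ["MED1"],
                "mediator_kind": ["splicing"], "proportion_mediated": [0.5],
                "total_effect": [1.0], "sex_effect": [0.0], "resid_sd": [1.0],
            },
            index=pd.Index(["T1"], name="trait_id"),
        )
        truth = sc.SimTruth(events=pd.DataFrame(), genes=pd.DataFrame(), traits=traits)
        with pytest.raises(ConfigurationError):
            sc.simulate_phenotypes(f2, med, truth, seed=1)


def test_end_to_end_determinism(f2):
    truth = sc.simulate_truth(f2.markers, n_events=10, n_genes=5, n_traits=2, seed=42)
    a = sc.simulate_junction_counts(f2, truth, 30, seed=43)
    b = sc.simulate_junction_counts(f2, truth, 30, seed=43)
    assert np.array_equal(a.inclusion, b.inclusion)
    ea = sc.simulate_expression(f2, truth, seed=44)
    eb = sc.simulate_expression(f2, truth, seed=44)
    pd.testing.assert_frame_equal(ea, eb)
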