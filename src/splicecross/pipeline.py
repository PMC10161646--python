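"""End-to-end orchestration: simulate -> quantify -> heritability -> QTL ->
mediation, with a single YAML-able configuration and a reproducibility
manifest.

Every stage writes plain TSV outputs into ``out_dir`` and the manifest
records a sha256 per file, so a re-run with the same config and seed can be
verified byte-for-byte. Stages are also exposed individually through the CLI
so a run can be resumed from any stage's inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix, JunctionCountTable, RunManifest, SimTruth
from .grm import compute_grm, write_grm
from .heritability import (
    GeneticCorrelationModel,
    fdr_adjust,
    fit_heritability_matrix,
    sex_covariate,
)
from .mediate import MediationModel, build_trios, significant_mediators
from .psi import filter_events, psi_matrix, quantile_normalize
from .scan import classify_cis_trans, forward_select, permutation_fdr, summarize_qtl
from . import io as sio
from .sim import (
    GenomeSpec,
    PedigreeSpec,
    simulate_expression,
    simulate_f2,
    simulate_founders,
    simulate_junction_counts,
    simulate_phenotypes,
    simulate_truth,
)

logger = logging.getLogger("splicecross.pipeline")


@dataclass
class SimulateConfig:
    n_founders_a: int = 10
    n_founders_b: int = 9
    n_f1: int = 35
    n_f2: int = 143
    n_chromosomes: int = 2
    chromosome_length: int = 50_000_000
    n_markers: int = 2000
    recombination_rate: float = 0.01
    fst: float = 0.15
    n_events: int = 500
    n_genes: int = 200
    n_traits: int = 5
    sqtl_fraction: float = 0.10
    eqtl_fraction: float = 0.15
    beta_event: float = 0.8
    beta_gene: float = 0.5
    coverage_mean: float = 50.0

    def pedigree(self) -> PedigreeSpec:
        return PedigreeSpec(self.n_founders_a, self.n_founders_b, self.n_f1, self.n_f2)

    def genome(self) -> GenomeSpec:
        chroms = [(str(i + 1), self.chromosome_length) for i in range(self.n_chromosomes)]
        return GenomeSpec(chroms, self.n_markers, self.recombination_rate)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the analysis the package models."""

    out_dir: str = "splicecross_run"
    seed: int = 0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    # input paths, used when simulate is None
    genotypes_vcf: str | None = None
    phenotypes_tsv: str | None = None
    junction_counts_tsv: str | None = None
    expression_tsv: str | None = None
    gene_coords_bed: str | None = None
    # filter thresholds (splice_quant defaults)
    min_reads: int = 2
    min_samples: int = 2
    min_total: int = 5
    min_cov_fraction: float = 0.5
    mad_min: float = 1.0
    log2var_min: float = 2.0
    skew_max: float = 1.1
    min_sex_fraction: float = 0.2
    # FDR targets
    fdr_h2: float = 0.01
    fdr_qtl: float = 0.01
    fdr_pqtl: float = 0.05
    fdr_mediation: float = 0.05
    n_perm: int = 200
    cis_window: int = 1_000_000
    maf_min: float = 0.01
    n_boot_mediation: int = 1000
    max_corr_pairs: int = 50

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimulateConfig(**self.simulate)
        for name in ("fdr_h2", "fdr_qtl", "fdr_pqtl", "fdr_mediation"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(
    genotypes: GenotypeMatrix,
    counts: JunctionCountTable | None = None,
    expression: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-file sanity report: one row per violation (empty when clean)."""
    issues = []
    gset = set(genotypes.samples)
    if counts is not None:
        for s in counts.samples:
            if s not in gset:
                issues.append(("counts", s, "sample missing from genotypes"))
        if (counts.inclusion < 0).any() or (counts.exclusion < 0).any():
            issues.append(("counts", NA_ID, "negative junction count"))
        if not np.issubdtype(counts.inclusion.dtype, np.integer):
            issues.append(("counts", NA_ID, "non-integer counts"))
        bad = counts.events["start"] > counts.events["end"]
        for eid in counts.events.index[bad]:
            issues.append(("counts", eid, "start > end"))
    if expression is not None:
        for s in expression.columns:
            if s not in gset:
                issues.append(("expression", s, "sample missing from genotypes"))
        if (expression.to_numpy(dtype=float) < 0).any():
            issues.append(("expression", NA_ID, "negative expression value"))
    if phenotypes is not None:
        for s in phenotypes.index:
            if s not in gset:
                issues.append(("phenotypes", s, "sample missing from genotypes"))
    return pd.DataFrame(issues, columns=["file", "id", "violation"])


NA_ID = "-"


def _stage(manifest_files: dict, out_dir: Path, name: str):
    path = out_dir / name
    manifest_files[name] = path
    return path


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage; returns the manifest (also written as JSON)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    files: dict[str, Path] = {}
    timestamps: dict[str, float] = {}

    # -- stage 1: data ------------------------------------------------------
    truth: SimTruth | None = None
    if config.simulate is not None:
        sc = config.simulate
        logger.info("stage simulate: F2 cross with %d markers", sc.n_markers)
        founders = simulate_founders(sc.pedigree(), sc.genome(), sc.fst, seed=rng_seed)
        geno, pedigree = simulate_f2(founders, sc.pedigree(), sc.genome(), seed=rng_seed + 1)
        truth = simulate_truth(
            geno.markers, n_events=sc.n_events, n_genes=sc.n_genes,
            n_traits=sc.n_traits, sqtl_fraction=sc.sqtl_fraction,
            eqtl_fraction=sc.eqtl_fraction, beta_event=sc.beta_event,
            beta_gene=sc.beta_gene, genotypes=geno, seed=rng_seed + 2,
        )
        counts = simulate_junction_counts(geno, truth, sc.coverage_mean, seed=rng_seed + 3)
        expression = simulate_expression(geno, truth, seed=rng_seed + 4)
        psi_for_pheno = psi_matrix(counts)
        mediators = pd.concat([psi_for_pheno, expression])
        phenotypes = simulate_phenotypes(geno, mediators, truth, seed=rng_seed + 5)
        gene_coords = truth.genes[["chrom", "start", "end"]].copy()
        sio.write_vcf(geno, _stage(files, out, "genotypes.vcf"))
        sio.write_marker_map(geno, _stage(files, out, "marker_map.tsv"))
        sio.write_table(pedigree, _stage(files, out, "pedigree.tsv"))
        sio.write_junction_counts(counts, _stage(files, out, "junction_counts.tsv"))
        sio.write_matrix(expression, _stage(files, out, "expression_tpm.tsv"), "gene_id")
        sio.write_matrix(phenotypes, _stage(files, out, "phenotypes.tsv"), "sample")
        sio.write_bed(gene_coords, _stage(files, out, "gene_coords.bed"))
        sio.write_matrix(truth.events, _stage(files, out, "truth_events.tsv"), "event_id")
        sio.write_matrix(truth.genes, _stage(files, out, "truth_genes.tsv"), "gene_id")
        sio.write_matrix(truth.traits, _stage(files, out, "truth_traits.tsv"), "trait_id")
    else:
        sex = None
        phenotypes = None
        if config.phenotypes_tsv:
            phenotypes = sio.read_matrix(config.phenotypes_tsv)
            if "sex" in phenotypes.columns:
                sex = phenotypes["sex"]
        geno = sio.read_vcf(config.genotypes_vcf, sex=sex)
        counts = sio.read_junction_counts(config.junction_counts_tsv)
        expression = (
            sio.read_matrix(config.expression_tsv) if config.expression_tsv else None
        )
        gene_coords = (
            sio.read_bed(config.gene_coords_bed) if config.gene_coords_bed else None
        )
    timestamps["data"] = time.time() - t0

    report = validate_inputs(
        geno, counts, expression, phenotypes if phenotypes is not None else None
    )
    sio.write_table(report, _stage(files, out, "validation_report.tsv"))
    if len(report):
        logger.warning("validate_inputs: %d violations", len(report))

    # -- stage 2: quantify & filter -----------------------------------------
    logger.info("stage quantify: %d events", counts.n_events)
    psi = psi_matrix(counts)
    filt = filter_events(
        counts, geno.sex,
        min_reads=config.min_reads, min_samples=config.min_samples,
        min_total=config.min_total, min_cov_fraction=config.min_cov_fraction,
        mad_min=config.mad_min, log2var_min=config.log2var_min,
        skew_max=config.skew_max, min_sex_fraction=config.min_sex_fraction,
    )
    kept_events = filt.index[filt["kept"]]
    sio.write_matrix(psi, _stage(files, out, "psi_matrix.tsv"), "event_id")
    sio.write_matrix(filt, _stage(files, out, "filter_report.tsv"), "event_id")

    def _qn_rows(mat: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for tid, row in mat.iterrows():
            try:
                rows[tid] = quantile_normalize(row.to_numpy(dtype=float))
            except ValueError:
                continue
        return pd.DataFrame.from_dict(rows, orient="index", columns=mat.columns)

    psi_qn = _qn_rows(psi.loc[kept_events])
    sio.write_matrix(psi_qn, _stage(files, out, "psi_qn.tsv"), "event_id")
    expr_qn = None
    if expression is not None:
        expr_qn = _qn_rows(expression)
        sio.write_matrix(expr_qn, _stage(files, out, "expression_qn.tsv"), "gene_id")
    timestamps["quantify"] = time.time() - t0

    # -- stage 3: heritability & genetic correlation ------------------------
    grm = compute_grm(geno, maf_min=config.maf_min)
    write_grm(grm, _stage(files, out, "grm.tsv"))
    sex_cov = sex_covariate(geno.sex)
    h2_psi = fit_heritability_matrix(psi_qn, grm, sex_cov)
    sio.write_matrix(h2_psi, _stage(files, out, "h2_splicing.tsv"), "event_id")
    h2_expr = None
    if expr_qn is not None:
        h2_expr = fit_heritability_matrix(expr_qn, grm, sex_cov)
        sio.write_matrix(h2_expr, _stage(files, out, "h2_expression.tsv"), "gene_id")
    logger.info(
        "stage h2: %d/%d splicing events significant at FDR %.2g",
        int((h2_psi.get("q", pd.Series(dtype=float)) <= config.fdr_h2).sum()),
        len(h2_psi), config.fdr_h2,
    )

    if expr_qn is not None and len(psi_qn) and "gene_id" in counts.events:
        pairs = []
        for eid in psi_qn.index:
            gid = counts.events.loc[eid, "gene_id"]
            if gid in expr_qn.index:
                pairs.append((eid, gid))
            if len(pairs) >= config.max_corr_pairs:
                break
        rows = []
        for eid, gid in pairs:
            try:
                res = GeneticCorrelationModel(
                    psi_qn.loc[eid].reindex(grm.index).to_numpy(float),
                    expr_qn.loc[gid].reindex(grm.index).to_numpy(float),
                    grm, sex_cov,
                ).fit()
            except (ValueError, np.linalg.LinAlgError):
                continue
            rows.append((eid, gid, res.r_g, res.se, res.r_e, res.lrt, res.pvalue))
        gc = pd.DataFrame(
            rows, columns=["event_id", "gene_id", "r_g", "se", "r_e", "LRT", "p"]
        )
        if len(gc):
            gc["q"] = fdr_adjust(gc["p"].fillna(1.0).to_numpy())
        sio.write_table(gc, _stage(files, out, "genetic_correlation.tsv"))
    timestamps["heritability"] = time.time() - t0

    # -- stage 4: sQTL / eQTL mapping ---------------------------------------
    def _map_molecular(mat: pd.DataFrame, label: str, coords: pd.DataFrame):
        if len(mat) < 2:
            return pd.DataFrame(columns=["trait", "marker", "kind"]), None
        stage_seed = rng_seed + {"sqtl": 7, "eqtl": 11}.get(label, 13)
        null, thr, observed = permutation_fdr(
            mat, geno, grm, sex_cov, n_perm=config.n_perm,
            target_fdr=config.fdr_qtl, seed=stage_seed,
        )
        pd.DataFrame(
            {
                "threshold": null.threshold_grid,
                "observed": null.observed_counts,
                "mean_permuted": null.perm_counts.mean(axis=0),
                "fdr": null.fdr,
            }
        ).to_csv(out / f"{label}_permutation_fdr.tsv", sep="\t", index=False)
        files[f"{label}_permutation_fdr.tsv"] = out / f"{label}_permutation_fdr.tsv"
        if thr is None:
            logger.info("stage qtlmap[%s]: none significant", label)
            return pd.DataFrame(columns=["trait", "marker", "kind"]), None
        sig = observed.significant(thr)
        sig["kind"] = "splicing" if label == "sqtl" else "expression"
        calls = []
        for trait, grp in sig.groupby("trait"):
            lam = float(observed.ratios[observed.traits.get_loc(trait)])
            kept = forward_select(
                mat.loc[trait], list(grp["marker"]), geno, grm, sex_cov,
                p_enter=thr, lam=lam,
            )
            for _, r in kept.iterrows():
                calls.append((trait, r["marker"], r["p_conditional"]))
        calls = pd.DataFrame(calls, columns=["trait", "marker", "p_conditional"])
        labeled = classify_cis_trans(calls, geno.markers, coords, config.cis_window)
        sio.write_table(sig, _stage(files, out, f"{label}_significant.tsv"))
        sio.write_table(labeled, _stage(files, out, f"{label}_calls.tsv"))
        summ = summarize_qtl(labeled)
        summ.to_frame("count").to_csv(out / f"{label}_summary.tsv", sep="\t")
        files[f"{label}_summary.tsv"] = out / f"{label}_summary.tsv"
        logger.info("stage qtlmap[%s]: threshold %.3g, %d retained calls",
                    label, thr, len(labeled))
        return sig[["trait", "marker", "kind"]], thr

    event_coords = counts.events.join(
        gene_coords, on="gene_id", rsuffix="_gene"
    )[["chrom_gene", "start_gene", "end_gene"]].rename(
        columns=lambda c: c.replace("_gene", "")
    ) if gene_coords is not None else pd.DataFrame(columns=["chrom", "start", "end"])

    sqtl_sig, _ = _map_molecular(psi_qn, "sqtl", event_coords)
    eqtl_sig = pd.DataFrame(columns=["trait", "marker", "kind"])
    if expr_qn is not None and gene_coords is not None:
        eqtl_sig, _ = _map_molecular(expr_qn, "eqtl", gene_coords)
    timestamps["qtlmap"] = time.time() - t0

    # -- stage 5 + 6: pQTL mapping and mediation ----------------------------
    if phenotypes is None or phenotypes.shape[1] <= 1:
        logger.info("no phenotypes: pQTL mapping and mediation skipped")
    else:
        traits = phenotypes.drop(columns=["sex"], errors="ignore").T
        null, thr, observed = permutation_fdr(
            traits, geno, grm, sex_cov, n_perm=config.n_perm,
            target_fdr=config.fdr_pqtl, seed=rng_seed + 17,
        )
        if thr is None:
            logger.info("stage pqtl: none significant; mediation skipped")
        else:
            pqtl_sig = observed.significant(thr)
            sio.write_table(pqtl_sig, _stage(files, out, "pqtl_significant.tsv"))
            mol_sig = pd.concat([sqtl_sig, eqtl_sig], ignore_index=True)
            trios = build_trios(pqtl_sig, mol_sig)
            mediators = pd.concat([psi, expression]) if expression is not None else psi
            rows = []
            for _, trio in trios.iterrows():
                if trio["mediator_id"] not in mediators.index:
                    continue
                g = geno.dosage[:, geno.markers.index.get_loc(trio["marker"])]
                y = phenotypes[trio["trait"]].reindex(geno.samples).to_numpy(float)
                m = mediators.loc[trio["mediator_id"]].reindex(geno.samples).to_numpy(float)
                try:
                    res = MediationModel(y, g, m, sex_cov).fit(
                        n_boot=config.n_boot_mediation, seed=rng_seed + 23
                    )
                except (ValueError, np.linalg.LinAlgError):
                    continue
                rows.append({
                    "marker": trio["marker"], "mediator_id": trio["mediator_id"],
                    "mediator_kind": trio["mediator_kind"], "trait": trio["trait"],
                    "p_unadjusted": res.p_unadjusted, "p_adjusted": res.p_adjusted,
                    "ACME": res.acme, "ADE": res.ade, "total": res.total,
                    "proportion_mediated": res.proportion,
                    "proportion_raw": res.proportion_raw,
                    "ci_low": res.ci_acme[0], "ci_high": res.ci_acme[1],
                    "p_mediation": res.pvalue,
                })
            med = pd.DataFrame(rows)
            sio.write_table(med, _stage(files, out, "mediation.tsv"))
            if len(med):
                sig_med = significant_mediators(med, fdr=config.fdr_mediation)
                sio.write_table(sig_med, _stage(files, out, "mediation_significant.tsv"))
                logger.info("stage mediate: %d/%d trios significant at FDR %.2g",
                            len(sig_med), len(med), config.fdr_mediation)
    timestamps["mediation"] = time.time() - t0

    # -- manifest ------------------------------------------------------------
    config.to_yaml(out / "config.yaml")
    files["config.yaml"] = out / "config.yaml"
    manifest = RunManifest(
        config_hash=config.hash(),
        seed=rng_seed,
        version=__version__,
        checksums={name: _sha256(path) for name, path in sorted(files.items())},
        timestamps=timestamps,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "config_hash": manifest.config_hash,
                "seed": manifest.seed,
                "version": manifest.version,
                "checksums": manifest.checksums,
                "stage_seconds": {k: round(v, 2) for k, v in timestamps.items()},
            },
            fh, indent=2, sort_keys=True,
        )
    logger.info("pipeline complete in %.1f s", time.time() - t0)
    return manifest
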