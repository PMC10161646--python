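"""Synthetic F2-intercross data with known ground truth.

Emulates the study design the package targets: two divergent founder breeds
crossed to F1 and then intercrossed to F2, genotyped on a chip-like marker
panel, with junction-count splicing traits, log-scale expression traits and
organismal phenotypes whose QTL effects are partly mediated by a molecular
trait. Every stochastic step is driven by a single integer seed so the whole
data set is byte-identical across runs.

Model summary
-------------
* Founder allele frequencies per breed follow a Balding-Nichols model around
  a shared ancestral frequency, with divergence controlled by ``fst``.
* Meiosis uses the Haldane map: crossover counts per chromosome are
  Poisson(length in Morgans), positions uniform, no interference.
* Latent PSI follows a logit-linear model
  ``logit(psi) = mu + beta * g + u + e`` with a polygenic term ``u`` drawn
  from N(0, h2 * G) (G the realized genomic relationship matrix) and
  residual variance 1 - h2, so ``h2`` is the logit-scale heritability of the
  non-QTL part.
* Junction reads: total ``T ~ Poisson(coverage)``; inclusion reads are
  Binomial(T, psi*L_I / (psi*L_I + (1-psi)*L_E)) — length-weighted so that
  the length-normalized PSI estimator is consistent for the simulating psi.
* Phenotypes: ``y = gamma * mediator + delta * g + sex effect + e`` with
  gamma, delta scaled so the expected proportion of the marker effect running
  through the mediator equals the requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import GenotypeMatrix, JunctionCountTable, SimTruth
from .grm import compute_grm

# Relative frequencies of the five rMATS event classes, matching the
# proportions typically seen in bulk muscle RNA-Seq.
EVENT_CLASS_PROBS = {"SE": 0.72, "MXE": 0.185, "RI": 0.04, "A3SS": 0.03, "A5SS": 0.025}


class ConfigurationError(ValueError):
    """Invalid simulation specification."""


@dataclass
class PedigreeSpec:
    """Counts for the founders -> F1 -> F2 design (default 10+9 -> 35 -> 143)."""

    n_founders_a: int = 10
    n_founders_b: int = 9
    n_f1: int = 35
    n_f2: int = 143

    def __post_init__(self) -> None:
        for name in ("n_founders_a", "n_founders_b", "n_f1", "n_f2"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_f2 < 2:
            raise ConfigurationError("n_f2 must be >= 2")


@dataclass
class GenomeSpec:
    """Marker panel layout.

    ``recombination_rate`` is in Morgans per Mb (default 0.01, i.e. the
    canonical 1 cM/Mb). Marker positions are evenly spaced within each
    chromosome, split across chromosomes proportionally to length.
    """

    chromosomes: list = field(default_factory=lambda: [("1", 50_000_000), ("2", 50_000_000)])
    n_markers: int = 2000
    recombination_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be >= 1")
        if self.recombination_rate < 0:
            raise ConfigurationError("recombination_rate must be >= 0")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has non-positive length")

    def marker_map(self) -> pd.DataFrame:
        """Deterministic marker map: id, chrom, pos (1-based)."""
        total = sum(length for _, length in self.chromosomes)
        counts = []
        for _, length in self.chromosomes:
            counts.append(int(round(self.n_markers * length / total)))
        # fix rounding so the total is exact
        counts[-1] += self.n_markers - sum(counts)
        rows = []
        for (name, length), k in zip(self.chromosomes, counts):
            step = length / (k + 1)
            for j in range(k):
                rows.append((f"M{name}_{j + 1:05d}", str(name), int((j + 1) * step)))
        df = pd.DataFrame(rows, columns=["marker", "chrom", "pos"]).set_index("marker")
        if (df.groupby("chrom")["pos"].diff().dropna() <= 0).any():
            raise ConfigurationError("marker positions must strictly increase")
        return df


def simulate_founders(
    spec: PedigreeSpec,
    genome: GenomeSpec,
    fst: float = 0.15,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Two founder breeds with Balding-Nichols divergence ``fst``.

    Ancestral frequencies are Uniform(0.1, 0.9); each breed's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p (identical to p when
    F = 0). Genotypes are Hardy-Weinberg within breed; phased haplotypes are
    retained for downstream meiosis.
    """
    if not 0 <= fst < 1:
        raise ConfigurationError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    markers = genome.marker_map()
    m = len(markers)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    if fst > 0:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_a = rng.beta(a, b)
        p_b = rng.beta(a, b)
    else:
        p_a = p_anc.copy()
        p_b = p_anc.copy()

    names, haps, sexes = [], [], []
    for group, n, p in (("A", spec.n_founders_a, p_a), ("B", spec.n_founders_b, p_b)):
        h = (rng.random((n, 2, m)) < p).astype(np.int8)
        haps.append(h)
        names += [f"F{group}{i + 1:02d}" for i in range(n)]
        sexes += ["M" if i % 2 == 0 else "F" for i in range(n)]
    hap = np.concatenate(haps, axis=0)
    return GenotypeMatrix(
        samples=names,
        sex=np.array(sexes, dtype=object),
        markers=markers,
        dosage=hap.sum(axis=1).astype(float),
        haplotypes=hap,
    )


def _chrom_blocks(markers: pd.DataFrame, genome: GenomeSpec):
    """(chrom name, length, marker index array, positions) per chromosome."""
    blocks = []
    for name, length in genome.chromosomes:
        mask = (markers["chrom"] == str(name)).to_numpy()
        blocks.append((str(name), length, np.where(mask)[0], markers["pos"].to_numpy()[mask]))
    return blocks


def _gamete(hap_pair: np.ndarray, blocks, rate: float, rng) -> np.ndarray:
    """One meiosis under the Haldane model (Poisson crossovers, uniform pos)."""
    gam = np.empty(hap_pair.shape[1], dtype=np.int8)
    for _, length, idx, pos in blocks:
        morgans = length / 1e6 * rate
        n_co = rng.poisson(morgans)
        cuts = np.sort(rng.uniform(0, length, size=n_co))
        start = rng.integers(2)
        which = (start + np.searchsorted(cuts, pos)) % 2
        gam[idx] = hap_pair[which, idx]
    return gam


def simulate_f2(
    founders: GenotypeMatrix,
    spec: PedigreeSpec,
    genome: GenomeSpec,
    seed: int | None = None,
    return_f1: bool = False,
):
    """F1 = A x B crosses, F2 = F1 x F1 matings; returns (F2 genotypes, pedigree).

    Founder breed membership is taken from the sample-name prefix written by
    :func:`simulate_founders` (``FA*`` / ``FB*``). With ``return_f1`` the F1
    generation's genotypes are appended to the return tuple.
    """
    if founders.haplotypes is None:
        raise ConfigurationError("founder haplotypes required for meiosis")
    rng = np.random.default_rng(seed)
    blocks = _chrom_blocks(founders.markers, genome)
    rate = genome.recombination_rate
    idx_a = [i for i, s in enumerate(founders.samples) if s.startswith("FA")]
    idx_b = [i for i, s in enumerate(founders.samples) if s.startswith("FB")]
    if not idx_a or not idx_b:
        raise ConfigurationError("founders must contain both breed groups (FA*/FB*)")

    ped_rows = [
        (s, "NA", "NA", "founder", founders.sex[i])
        for i, s in enumerate(founders.samples)
    ]
    f1_haps = np.empty((spec.n_f1, 2, founders.n_markers), dtype=np.int8)
    f1_names = []
    for i in range(spec.n_f1):
        sire = idx_a[i % len(idx_a)]
        dam = idx_b[i % len(idx_b)]
        f1_haps[i, 0] = _gamete(founders.haplotypes[sire], blocks, rate, rng)
        f1_haps[i, 1] = _gamete(founders.haplotypes[dam], blocks, rate, rng)
        name = f"F1_{i + 1:03d}"
        f1_names.append(name)
        ped_rows.append((name, founders.samples[sire], founders.samples[dam], "F1", "M" if i % 2 == 0 else "F"))

    f2_haps = np.empty((spec.n_f2, 2, founders.n_markers), dtype=np.int8)
    f2_names, f2_sex = [], []
    for i in range(spec.n_f2):
        sire, dam = rng.choice(spec.n_f1, size=2, replace=False) if spec.n_f1 > 1 else (0, 0)
        f2_haps[i, 0] = _gamete(f1_haps[sire], blocks, rate, rng)
        f2_haps[i, 1] = _gamete(f1_haps[dam], blocks, rate, rng)
        name = f"F2_{i + 1:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        f2_names.append(name)
        f2_sex.append(sex)
        ped_rows.append((name, f1_names[sire], f1_names[dam], "F2", sex))

    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation", "sex"])
    f2 = GenotypeMatrix(
        samples=f2_names,
        sex=np.array(f2_sex, dtype=object),
        markers=founders.markers,
        dosage=f2_haps.sum(axis=1).astype(float),
        haplotypes=f2_haps,
    )
    if return_f1:
        f1 = GenotypeMatrix(
            samples=f1_names,
            sex=np.array(["M" if i % 2 == 0 else "F" for i in range(spec.n_f1)], dtype=object),
            markers=founders.markers,
            dosage=f1_haps.sum(axis=1).astype(float),
            haplotypes=f1_haps,
        )
        return f2, pedigree, f1
    return f2, pedigree


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

def simulate_truth(
    markers: pd.DataFrame,
    n_events: int = 500,
    n_genes: int = 200,
    n_traits: int = 5,
    sqtl_fraction: float = 0.10,
    eqtl_fraction: float = 0.15,
    h2_event: tuple[float, float] = (0.1, 0.5),
    h2_gene: tuple[float, float] = (0.1, 0.6),
    beta_event: float = 0.8,
    beta_gene: float = 0.5,
    cis_fraction: float = 0.8,
    proportions_mediated: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    sex_effect: float = 0.5,
    total_effect: float = 1.0,
    genotypes: GenotypeMatrix | None = None,
    seed: int | None = None,
) -> SimTruth:
    """Random but reproducible ground-truth tables.

    Genes are placed uniformly along the marker map's chromosomes; each event
    belongs to a gene and inherits its locus. A fraction of events/genes get
    a planted QTL, cis (within 1 Mb of the gene) with probability
    ``cis_fraction``, otherwise anywhere. Traits cycle through
    ``proportions_mediated`` and each uses a QTL-bearing molecular trait as
    its mediator, so mediation analysis has planted positives at known
    proportions. When ``genotypes`` are supplied, planted QTL markers are
    drawn only from markers polymorphic in that cohort, so every planted
    effect is realizable.
    """
    rng = np.random.default_rng(seed)
    chroms = markers["chrom"].unique()
    chrom_span = {c: int(markers.loc[markers["chrom"] == c, "pos"].max()) for c in chroms}

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    g_chrom = rng.choice(chroms, size=n_genes)
    g_start = np.array([rng.integers(1, max(2, chrom_span[c] - 100_000)) for c in g_chrom])
    g_len = rng.integers(5_000, 100_000, size=n_genes)
    genes = pd.DataFrame(
        {
            "chrom": g_chrom,
            "start": g_start,
            "end": g_start + g_len,
            "mu": rng.uniform(0.5, 5.0, size=n_genes),
            "h2": rng.uniform(*h2_gene, size=n_genes),
            "eqtl_marker": pd.array([pd.NA] * n_genes, dtype="string"),
            "beta": 0.0,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    if genotypes is not None:
        poly = np.nanstd(genotypes.dosage, axis=0) > 0
    else:
        poly = np.ones(len(markers), dtype=bool)

    def _pick_marker(chrom, start, end, cis):
        pos = markers["pos"].to_numpy()
        on_chrom = (markers["chrom"] == chrom).to_numpy() & poly
        if cis:
            near = on_chrom & (pos >= start - 1_000_000) & (pos <= end + 1_000_000)
            pool = np.where(near)[0]
            if len(pool) == 0:
                pool = np.where(on_chrom)[0]
        else:
            pool = np.where(poly)[0]
        if len(pool) == 0:
            raise ConfigurationError("no polymorphic marker available for QTL placement")
        return markers.index[rng.choice(pool)]

    has_eqtl = rng.random(n_genes) < eqtl_fraction
    for i in np.where(has_eqtl)[0]:
        cis = rng.random() < cis_fraction
        genes.iloc[i, genes.columns.get_loc("eqtl_marker")] = _pick_marker(
            genes["chrom"].iloc[i], genes["start"].iloc[i], genes["end"].iloc[i], cis
        )
        genes.iloc[i, genes.columns.get_loc("beta")] = beta_gene * rng.choice([-1, 1])

    event_ids = [f"E{i + 1:05d}" for i in range(n_events)]
    parent = rng.integers(0, n_genes, size=n_events)
    classes = rng.choice(
        list(EVENT_CLASS_PROBS), size=n_events, p=list(EVENT_CLASS_PROBS.values())
    )
    e_start = genes["start"].to_numpy()[parent] + rng.integers(0, 4_000, size=n_events)
    events = pd.DataFrame(
        {
            "gene_id": np.array(gene_ids, dtype=object)[parent],
            "event_class": classes,
            "chrom": genes["chrom"].to_numpy()[parent],
            "start": e_start,
            "end": e_start + rng.integers(100, 5_000, size=n_events),
            "inclusion_length": rng.integers(100, 300, size=n_events),
            "exclusion_length": rng.integers(50, 150, size=n_events),
            "mu": logit(rng.uniform(0.15, 0.85, size=n_events)),
            "h2": rng.uniform(*h2_event, size=n_events),
            "sqtl_marker": pd.array([pd.NA] * n_events, dtype="string"),
            "beta": 0.0,
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    has_sqtl = rng.random(n_events) < sqtl_fraction
    for i in np.where(has_sqtl)[0]:
        cis = rng.random() < cis_fraction
        events.iloc[i, events.columns.get_loc("sqtl_marker")] = _pick_marker(
            events["chrom"].iloc[i], events["start"].iloc[i], events["end"].iloc[i], cis
        )
        events.iloc[i, events.columns.get_loc("beta")] = beta_event * rng.choice([-1, 1])

    # traits: prefer QTL-bearing events as mediators, fall back to genes
    med_events = [e for e in event_ids if pd.notna(events.loc[e, "sqtl_marker"])]
    med_genes = [g for g in gene_ids if pd.notna(genes.loc[g, "eqtl_marker"])]
    rows = []
    for t in range(n_traits):
        prop = proportions_mediated[t % len(proportions_mediated)]
        if med_events and (t % 2 == 0 or not med_genes):
            mid = med_events[t % len(med_events)]
            kind, marker = "splicing", events.loc[mid, "sqtl_marker"]
        elif med_genes:
            mid = med_genes[t % len(med_genes)]
            kind, marker = "expression", genes.loc[mid, "eqtl_marker"]
        else:
            raise ConfigurationError("no QTL-bearing molecular trait to mediate through")
        rows.append((f"T{t + 1:02d}", marker, mid, kind, prop, total_effect, sex_effect, 1.0))
    traits = pd.DataFrame(
        rows,
        columns=[
            "trait_id", "pqtl_marker", "mediator_id", "mediator_kind",
            "proportion_mediated", "total_effect", "sex_effect", "resid_sd",
        ],
    ).set_index("trait_id")
    return SimTruth(events=events, genes=genes, traits=traits, seed=seed)


# ---------------------------------------------------------------------------
# Molecular traits and phenotypes
# ---------------------------------------------------------------------------

def _polygenic_factor(genotypes: GenotypeMatrix) -> np.ndarray:
    """Matrix L with L L' = G (realized GRM), for drawing u ~ N(0, h2 G)."""
    grm = compute_grm(genotypes, maf_min=0.0)
    d, u = np.linalg.eigh(grm.values)
    return u * np.sqrt(np.clip(d, 0, None))


def _marker_dosage(genotypes: GenotypeMatrix, marker) -> np.ndarray:
    g = genotypes.dosage[:, genotypes.markers.index.get_loc(marker)]
    return np.nan_to_num(g, nan=float(np.nanmean(g)))


def simulate_junction_counts(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    coverage_mean: float = 50.0,
    seed: int | None = None,
) -> JunctionCountTable:
    """Junction counts whose expected PSI follows the logit-linear model.

    The inclusion-read probability is length-weighted,
    ``psi L_I / (psi L_I + (1 - psi) L_E)``, precisely so that the
    length-normalized PSI estimator applied to the counts is consistent for
    the latent psi. Samples with zero total reads yield (0, 0) counts, i.e.
    a missing PSI, never an imputed zero.
    """
    if coverage_mean <= 0:
        raise ConfigurationError("coverage_mean must be > 0")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    L = _polygenic_factor(genotypes)
    ev = truth.events
    inc = np.zeros((len(ev), n), dtype=np.int64)
    exc = np.zeros_like(inc)
    for j, (eid, row) in enumerate(ev.iterrows()):
        eta = np.full(n, row["mu"], dtype=float)
        if pd.notna(row["sqtl_marker"]):
            g = _marker_dosage(genotypes, row["sqtl_marker"])
            eta += row["beta"] * (g - g.mean())
        h2 = float(row["h2"])
        eta += np.sqrt(h2) * (L @ rng.standard_normal(n))
        eta += np.sqrt(1 - h2) * rng.standard_normal(n)
        psi = expit(eta)
        total = rng.poisson(coverage_mean, size=n)
        li, le = row["inclusion_length"], row["exclusion_length"]
        p_inc = psi * li / (psi * li + (1 - psi) * le)
        inc[j] = rng.binomial(total, p_inc)
        exc[j] = total - inc[j]
    meta = ev[
        ["gene_id", "event_class", "chrom", "start", "end",
         "inclusion_length", "exclusion_length"]
    ].copy()
    return JunctionCountTable(
        events=meta, samples=list(genotypes.samples), inclusion=inc, exclusion=exc
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """TPM-like expression: log-scale linear genetic model, exponentiated."""
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    L = _polygenic_factor(genotypes)
    out = np.empty((len(truth.genes), n))
    for j, (gid, row) in enumerate(truth.genes.iterrows()):
        eta = np.full(n, row["mu"], dtype=float)
        if pd.notna(row["eqtl_marker"]):
            g = _marker_dosage(genotypes, row["eqtl_marker"])
            eta += row["beta"] * (g - g.mean())
        h2 = float(row["h2"])
        eta += np.sqrt(h2) * (L @ rng.standard_normal(n))
        eta += np.sqrt(1 - h2) * rng.standard_normal(n)
        out[j] = np.exp(eta)
    return pd.DataFrame(out, index=truth.genes.index, columns=genotypes.samples)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    mediators: pd.DataFrame,
    truth: SimTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Phenotypes with a planted, partially mediated pQTL.

    For each trait the mediator path coefficient ``gamma`` and the direct
    marker effect ``delta`` are scaled against the *realized* slope ``a`` of
    the mediator on the marker, so that the expected proportion mediated of
    the total per-allele effect equals ``truth.traits.proportion_mediated``.
    Returns a samples x (sex + traits) table.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    med = mediators.reindex(columns=genotypes.samples)
    out = pd.DataFrame(index=pd.Index(genotypes.samples, name="sample"))
    out["sex"] = genotypes.sex
    sex_ind = (genotypes.sex == "M").astype(float)
    for tid, row in truth.traits.iterrows():
        if row["mediator_id"] not in med.index:
            raise ConfigurationError(f"mediator {row['mediator_id']} not in mediator matrix")
        m = med.loc[row["mediator_id"]].to_numpy(dtype=float)
        m = np.where(np.isnan(m), np.nanmean(m), m)
        if np.nanstd(m) == 0:
            raise ConfigurationError(f"mediator {row['mediator_id']} has zero variance")
        g = _marker_dosage(genotypes, row["pqtl_marker"])
        gc = g - g.mean()
        denom = float(np.dot(gc, gc))
        if denom == 0.0:
            raise ConfigurationError(
                f"trait {tid}: pQTL marker {row['pqtl_marker']} is monomorphic"
            )
        a = float(np.dot(gc, m - m.mean()) / denom)
        prop, tau = float(row["proportion_mediated"]), float(row["total_effect"])
        if prop > 0 and abs(a) < 1e-12:
            raise ConfigurationError(
                f"trait {tid}: mediator has no marker effect, cannot mediate"
            )
        gamma = prop * tau / a if prop > 0 else 0.0
        delta = (1 - prop) * tau
        y = (
            gamma * m
            + delta * g
            + float(row["sex_effect"]) * sex_ind
            + rng.normal(0.0, float(row["resid_sd"]), size=n)
        )
        out[tid] = y
    return out
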