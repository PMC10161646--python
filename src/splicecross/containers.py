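"""In-memory containers shared across the package.

Conventions
-----------
* Sample-by-marker dosage matrices are float arrays coded 0/1/2 with NaN for
  missing genotypes.
* Coordinates are 1-based inclusive (GTF convention) everywhere internally.
* Molecular-trait matrices (PSI, expression) are pandas DataFrames with
  traits as rows and samples as columns; missing values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_CLASSES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for a cohort with a marker map and per-sample sex.

    Parameters
    ----------
    samples : list of str
        Sample identifiers (rows of ``dosage``).
    sex : ndarray of str
        ``"M"`` or ``"F"`` per sample.
    markers : DataFrame
        Indexed by marker id with columns ``chrom`` and ``pos`` (1-based),
        sorted by (chrom, pos).
    dosage : ndarray, shape (n_samples, n_markers)
        Alternate-allele dosage in {0, 1, 2}; NaN marks missing calls.
    haplotypes : ndarray, shape (n_samples, 2, n_markers), optional
        Phased haplotypes (0/1 alternate-allele indicator). Carried by the
        simulator so that meiosis can act on true phase; absent for data
        read from unphased sources.
    """

    samples: list[str]
    sex: np.ndarray
    markers: pd.DataFrame
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker count does not match dosage columns")
        if self.markers.index.duplicated().any():
            raise ValueError("duplicate marker ids")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0/1/2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        hap = None if self.haplotypes is None else self.haplotypes[idx]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in np.atleast_1d(idx)],
            sex=self.sex[idx],
            markers=self.markers,
            dosage=self.dosage[idx],
            haplotypes=hap,
        )


@dataclass
class JunctionCountTable:
    """rMATS-style inclusion/exclusion junction counts per splice event.

    ``events`` is indexed by event id with columns ``gene_id``,
    ``event_class`` (one of SE/RI/A5SS/A3SS/MXE), ``chrom``, ``start``,
    ``end``, ``inclusion_length`` and ``exclusion_length`` (effective form
    lengths in bp). ``inclusion``/``exclusion`` are integer arrays with shape
    (n_events, n_samples).
    """

    events: pd.DataFrame
    samples: list[str]
    inclusion: np.ndarray
    exclusion: np.ndarray

    def __post_init__(self) -> None:
        self.inclusion = np.asarray(self.inclusion)
        self.exclusion = np.asarray(self.exclusion)
        if self.inclusion.shape != self.exclusion.shape:
            raise ValueError("inclusion/exclusion shapes differ")
        if self.inclusion.shape != (len(self.events), len(self.samples)):
            raise ValueError("count shape does not match events x samples")
        if (self.inclusion < 0).any() or (self.exclusion < 0).any():
            raise ValueError("negative junction counts")
        bad = ~self.events["event_class"].isin(EVENT_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown event class: {self.events['event_class'][bad].unique()}"
            )
        if (self.events["inclusion_length"] <= 0).any() or (
            self.events["exclusion_length"] <= 0
        ).any():
            raise ValueError("form lengths must be positive")

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class SimTruth:
    """Ground-truth tables for a synthetic data set.

    events : DataFrame indexed by event id
        ``h2`` (logit-scale polygenic heritability), ``sqtl_marker`` (id or
        NaN), ``beta`` (allelic effect on logit PSI), ``mu`` (logit-scale
        intercept).
    genes : DataFrame indexed by gene id
        ``h2``, ``eqtl_marker``, ``beta``, ``mu`` on the log-expression scale.
    traits : DataFrame indexed by trait id
        ``pqtl_marker``, ``mediator_id``, ``mediator_kind`` (splicing or
        expression), ``proportion_mediated`` in [0, 1], ``total_effect`` (per
        allele on the trait scale), ``sex_effect``, ``resid_sd``.
    """

    events: pd.DataFrame
    genes: pd.DataFrame
    traits: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.traits):
            pm = self.traits["proportion_mediated"].dropna()
            if ((pm < 0) | (pm > 1)).any():
                raise ValueError("proportion_mediated must lie in [0, 1]")


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, seed, per-file checksums."""

    config_hash: str
    seed: int
    version: str
    checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
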