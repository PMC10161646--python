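"""Genomic relationship matrix (VanRaden method 1)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def compute_grm(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_policy: str = "mean",
) -> pd.DataFrame:
    """G = Z Z' / (2 * sum_k p_k (1 - p_k)) with Z the centered dosages.

    Markers with minor-allele frequency below ``maf_min`` are dropped;
    missing dosages are imputed with the per-marker mean (``missing_policy``
    currently supports only ``"mean"``). Under Hardy-Weinberg the diagonal
    averages ~1. Returns a symmetric samples x samples DataFrame.
    """
    if missing_policy != "mean":
        raise ValueError(f"unknown missing_policy: {missing_policy}")
    X = genotypes.dosage.copy()
    p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = np.isfinite(p) & (maf >= maf_min) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic markers after MAF filter")
    X = X[:, keep]
    p = p[keep]
    # mean imputation, then center at 2p
    col_mean = 2.0 * p
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    Z = X - col_mean
    denom = 2.0 * np.sum(p * (1 - p))
    G = Z @ Z.T / denom
    G = (G + G.T) / 2.0
    return pd.DataFrame(G, index=genotypes.samples, columns=genotypes.samples)


def write_grm(grm: pd.DataFrame, path) -> None:
    grm.to_csv(path, sep="\t", index_label="sample")


def read_grm(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
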