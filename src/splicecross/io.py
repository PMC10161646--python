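"""Readers and writers for the on-disk formats.

All tabular outputs are TSV with explicit headers and ``NA`` for missing
values; genotypes go to/from VCF (GT field) plus a TSV marker map; gene or
event coordinates come from BED (0-based half-open, converted on read) or a
minimal GTF gene track. Coordinates are 1-based inclusive in memory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, JunctionCountTable

NA = "NA"

RMATS_COLUMNS = [
    "event_id", "gene_id", "event_class", "chrom", "start", "end",
    "IncFormLen", "SkipFormLen",
]


# -- genotypes ---------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT only; phased when haplotypes are available."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(genotypes.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        hap = genotypes.haplotypes
        for j, (mid, row) in enumerate(genotypes.markers.iterrows()):
            if hap is not None:
                gts = [f"{hap[i, 0, j]}|{hap[i, 1, j]}" for i in range(genotypes.n_samples)]
            else:
                lut = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                gts = [
                    lut.get(genotypes.dosage[i, j], "./.")
                    for i in range(genotypes.n_samples)
                ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path, sex: pd.Series | None = None) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix` (via cyvcf2).

    ``sex`` maps sample id to M/F; unspecified samples default to ``F``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_rows = []
    dosages = []
    for var in vcf:
        marker_rows.append((var.ID, var.CHROM, var.POS))
        # with gts012: gt_types 0/1/2 are the alt dosage, 3 is missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosages.append(gt)
    vcf.close()
    markers = pd.DataFrame(marker_rows, columns=["marker", "chrom", "pos"]).set_index("marker")
    sex_arr = np.array(
        [sex.get(s, "F") if sex is not None else "F" for s in samples], dtype=object
    )
    return GenotypeMatrix(
        samples=samples, sex=sex_arr, markers=markers,
        dosage=np.array(dosages, dtype=float).T,
    )


def write_marker_map(genotypes: GenotypeMatrix, path) -> None:
    genotypes.markers.to_csv(path, sep="\t", index_label="marker", na_rep=NA)


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        genotypes.dosage.T, index=genotypes.markers.index, columns=genotypes.samples
    ).to_csv(path, sep="\t", index_label="marker", na_rep=NA)


def read_dosage_tsv(path, map_path, sex: pd.Series | None = None) -> GenotypeMatrix:
    dm = pd.read_csv(path, sep="\t", index_col=0, na_values=NA)
    markers = pd.read_csv(map_path, sep="\t", index_col=0, na_values=NA)
    markers = markers.loc[dm.index]
    samples = list(dm.columns)
    sex_arr = np.array(
        [sex.get(s, "F") if sex is not None else "F" for s in samples], dtype=object
    )
    return GenotypeMatrix(
        samples=samples, sex=sex_arr, markers=markers,
        dosage=dm.to_numpy(dtype=float).T,
    )


# -- junction counts (rMATS-style) ------------------------------------------

def write_junction_counts(counts: JunctionCountTable, path) -> None:
    """One row per event: metadata, then per-sample IJC_/SJC_ columns."""
    meta = counts.events.rename(
        columns={"inclusion_length": "IncFormLen", "exclusion_length": "SkipFormLen"}
    )
    inc = pd.DataFrame(
        counts.inclusion, index=meta.index,
        columns=[f"IJC_{s}" for s in counts.samples],
    )
    exc = pd.DataFrame(
        counts.exclusion, index=meta.index,
        columns=[f"SJC_{s}" for s in counts.samples],
    )
    df = pd.concat([meta, inc, exc], axis=1)
    df.to_csv(path, sep="\t", index_label="event_id", na_rep=NA)


def read_junction_counts(path) -> JunctionCountTable:
    df = pd.read_csv(path, sep="\t", index_col="event_id", na_values=NA)
    samples = [c[4:] for c in df.columns if c.startswith("IJC_")]
    inc = df[[f"IJC_{s}" for s in samples]].to_numpy(dtype=np.int64)
    exc = df[[f"SJC_{s}" for s in samples]].to_numpy(dtype=np.int64)
    events = df[["gene_id", "event_class", "chrom", "start", "end",
                 "IncFormLen", "SkipFormLen"]].rename(
        columns={"IncFormLen": "inclusion_length", "SkipFormLen": "exclusion_length"}
    )
    return JunctionCountTable(events=events, samples=samples, inclusion=inc, exclusion=exc)


# -- matrices / tables -------------------------------------------------------

def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep=NA)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=NA)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA)


# -- coordinates -------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED -> 1-based inclusive coordinates indexed by the name column."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return df.set_index("name")[["chrom", "start", "end"]]


def write_bed(coords: pd.DataFrame, path) -> None:
    """1-based inclusive coordinates (chrom/start/end, indexed by name) -> BED."""
    with open(path, "w") as fh:
        for name, row in coords.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{name}\n")


def read_gtf_genes(path) -> pd.DataFrame:
    """Gene records of a GTF -> chrom/start/end indexed by gene_id."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";") if kv.strip()
            )
            rows.append((attrs.get("gene_id", NA), f[0], int(f[3]), int(f[4])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).set_index("gene_id")
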