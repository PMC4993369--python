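"""Gene annotation: coordinates, strand, functional category, SM-cluster membership.

Internal coordinates are 0-based half-open throughout the package (the native
bedGraph/BED convention); GFF3 (1-based inclusive) is converted on read and
write.  Genes carry one of two functional categories: ``CSF`` ("cell structure
and function", i.e. basic metabolism) or ``SM`` (secondary-metabolite cluster
genes, physically contiguous runs tagged with a cluster id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_category_map",
    "write_category_map",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand", "category", "cluster_id"]


@dataclass
class GenomeAnnotation:
    """Gene table indexed by gene id plus chromosome lengths.

    ``genes`` columns: chrom, start, end (0-based half-open), strand (+/-),
    category (CSF|SM), cluster_id (nullable integer).
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.genes.index.has_duplicates:
            dupes = self.genes.index[self.genes.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        g = self.genes
        if (g["end"] <= g["start"]).any():
            raise ValueError("gene with end <= start")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        for chrom, sub in g.groupby("chrom"):
            if chrom not in self.chrom_lengths:
                raise ValueError(f"gene on unknown chromosome {chrom!r}")
            if (sub["end"] > self.chrom_lengths[chrom]).any():
                raise ValueError(f"gene beyond end of {chrom}")

    @property
    def atg(self) -> pd.Series:
        """Translation-start anchor: ``start`` on +, ``end`` on - (half-open frame)."""
        return self.genes["start"].where(self.genes["strand"] == "+", self.genes["end"])

    @property
    def stop_codon(self) -> pd.Series:
        """Stop-codon anchor: ``end`` on +, ``start`` on -."""
        return self.genes["end"].where(self.genes["strand"] == "+", self.genes["start"])

    @property
    def orf_length(self) -> pd.Series:
        return self.genes["end"] - self.genes["start"]

    def category_members(self, category: str) -> pd.Index:
        return self.genes.index[self.genes["category"] == category]

    def cluster_extents(self) -> pd.DataFrame:
        """Coordinate span of each SM cluster (outermost gene boundaries)."""
        sm = self.genes[self.genes["cluster_id"].notna()]
        if sm.empty:
            return pd.DataFrame(columns=["chrom", "start", "end", "n_genes"])
        rows = []
        for cid, sub in sm.groupby("cluster_id"):
            chroms = sub["chrom"].unique()
            if len(chroms) != 1:
                raise ValueError(f"cluster {cid} spans multiple chromosomes")
            rows.append(
                {
                    "cluster_id": int(cid),
                    "chrom": chroms[0],
                    "start": int(sub["start"].min()),
                    "end": int(sub["end"].max()),
                    "n_genes": len(sub),
                }
            )
        return pd.DataFrame(rows).set_index("cluster_id")

    def mirrored(self) -> "GenomeAnnotation":
        """Coordinate-mirrored genome (x -> L - x, strands flipped): test utility."""
        g = self.genes.copy()
        L = g["chrom"].map(self.chrom_lengths)
        start = L - g["end"]
        end = L - g["start"]
        g["start"], g["end"] = start, end
        g["strand"] = np.where(g["strand"] == "+", "-", "+")
        return GenomeAnnotation(g, dict(self.chrom_lengths))


def read_gff3(path, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open).

    Chromosome lengths are taken from ``##sequence-region`` pragmas unless
    given explicitly.  Category/cluster attributes written by this package are
    recovered; absent attributes default to CSF / no cluster.
    """
    pragma_lengths: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, start, end = line.split()[:4]
                pragma_lengths[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            cid = attrs.get("cluster_id")
            rows.append(
                {
                    "gene_id": attrs.get("ID", f"gene{len(rows)}"),
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                    "category": attrs.get("category", "CSF"),
                    "cluster_id": float(cid) if cid not in (None, ".") else np.nan,
                }
            )
    genes = pd.DataFrame(rows).set_index("gene_id")
    lengths = chrom_lengths if chrom_lengths is not None else pragma_lengths
    if not lengths:
        raise ValueError("no chromosome lengths: GFF3 lacks ##sequence-region pragmas")
    return GenomeAnnotation(genes, dict(lengths))


def write_gff3(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for gid, row in ann.genes.sort_values(["chrom", "start"]).iterrows():
            cid = "." if pd.isna(row["cluster_id"]) else str(int(row["cluster_id"]))
            attrs = f"ID={gid};category={row['category']};cluster_id={cid}"
            fh.write(
                f"{row['chrom']}\tchromtx\tgene\t{row['start'] + 1}\t{row['end']}\t.\t"
                f"{row['strand']}\t.\t{attrs}\n"
            )


def read_bed(path, chrom_lengths: dict[str, int]) -> GenomeAnnotation:
    """Read genes from BED6 (categories default to CSF; no cluster info)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    genes = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"],
            "category": "CSF",
            "cluster_id": np.nan,
        }
    )
    genes.index = pd.Index(df["name"], name="gene_id")
    return GenomeAnnotation(genes, dict(chrom_lengths))


def write_bed(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gid, row in ann.genes.sort_values(["chrom", "start"]).iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{gid}\t0\t{row['strand']}\n"
            )


def read_category_map(path) -> pd.DataFrame:
    """Read a gene functional-category map TSV: gene_id, category, cluster_id."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    if "category" not in df.columns:
        raise ValueError("category map needs a 'category' column")
    return df


def write_category_map(ann: GenomeAnnotation, path) -> None:
    out = ann.genes[["category", "cluster_id"]].copy()
    out.to_csv(path, sep="\t", index_label="gene_id")
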