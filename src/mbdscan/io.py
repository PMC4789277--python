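"""Readers and writers for the plain-text formats the pipeline exchanges.

Intervals travel as BED (3/6/12 columns, 0-based half-open, tab-separated,
no header); tables as TSV with a header line. Direction codes ("01"/"10")
are always read back as strings.
"""
from __future__ import annotations

import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, ToyGenome

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path) -> ToyGenome:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return ToyGenome(tuple((str(r.chrom), int(r.length)) for r in df.itertuples()))


def write_chrom_sizes(genome: ToyGenome, path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    """Read a headerless BED3/BED6 file into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    strand_col = "strand" in df.columns
    return [
        GenomicInterval(
            str(r.chrom),
            int(r.start),
            int(r.end),
            str(r.strand) if strand_col else ".",
        )
        for r in df.itertuples(index=False)
    ]


def read_bed12(path) -> list[GeneModel]:
    """Read gene models from BED12 (name field = 'gene_id|symbol' or id)."""
    genes: list[GeneModel] = []
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 3: str})
    if df.empty:
        return genes
    for r in df.itertuples(index=False):
        chrom, start, end, name = str(r[0]), int(r[1]), int(r[2]), str(r[3])
        strand = str(r[5])
        n_blocks = int(r[9])
        sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(r[11]).rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(f"malformed BED12 block fields for {name}")
        exons = tuple((start + s, start + s + w) for s, w in zip(starts, sizes))
        gene_id, _, symbol = name.partition("|")
        genes.append(
            GeneModel(gene_id, symbol or gene_id, chrom, strand, start, end, exons)
        )
    return genes


def write_bed12(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.tx_start) for s, e in g.exons)
        rows.append(
            [
                g.chrom,
                g.tx_start,
                g.tx_end,
                f"{g.gene_id}|{g.symbol}",
                0,
                g.strand,
                g.tx_start,
                g.tx_end,
                "0,0,0",
                len(g.exons),
                sizes,
                starts,
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"direction": str, "chrom": str})
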