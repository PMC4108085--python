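"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open throughout the package, which is
BED-native. Every reader and writer is gzip-tolerant: a ``.gz`` suffix switches
to transparent compression.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open *path*, transparently gzipped if it ends in ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into an ordered {name: uppercase sequence} dict."""
    with xopen(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with xopen(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


# -- FASTQ ------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) tuples."""
    with xopen(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> int:
    """Write (name, sequence) pairs as FASTQ with uniform dummy qualities.

    Returns the number of reads written.
    """
    n = 0
    with xopen(path, "wt") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


# -- BED --------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3..BED6 into a DataFrame with BED6 columns (missing ones filled)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in [("name", "."), ("score", 0), ("strand", ".")]:
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with at least chrom/start/end (optionally name, score, strand) as BED."""
    cols = [c for c in BED6_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


# -- gene models (BED12 / refGene-style TSV) --------------------------------

BED12_COLUMNS = BED6_COLUMNS + [
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def write_genes_bed12(genes, path: str | Path) -> None:
    """Write GeneModel records (see :mod:`mscc.annotate`) as BED12."""
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        starts = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
        rows.append(
            [g.chrom, g.tx_start, g.tx_end, g.name, 0, g.strand,
             g.tx_start, g.tx_end, "0,0,0", len(g.exons), sizes, starts]
        )
    pd.DataFrame(rows, columns=BED12_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path: str | Path):
    """Read BED12 gene models. Returns a list of GeneModel."""
    from .annotate import GeneModel

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected 12 BED columns, got {df.shape[1]}")
    df.columns = BED12_COLUMNS
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = [(row.start + s, row.start + s + sz) for s, sz in zip(starts, sizes)]
        genes.append(GeneModel(name=row.name, chrom=row.chrom, strand=row.strand,
                               tx_start=int(row.start), tx_end=int(row.end), exons=exons))
    return genes


REFGENE_COLUMNS = ["name", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds"]


def read_genes_refgene(path: str | Path):
    """Read a UCSC refGene-like TSV (0-based txStart, comma lists of exon bounds)."""
    from .annotate import GeneModel

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REFGENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing refGene columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exonStarts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exonEnds).rstrip(",").split(",")]
        genes.append(GeneModel(name=row.name, chrom=row.chrom, strand=row.strand,
                               tx_start=int(row.txStart), tx_end=int(row.txEnd),
                               exons=list(zip(starts, ends))))
    return genes


def read_genes(path: str | Path):
    """Read gene models from BED12 or refGene-style TSV, sniffing the shape."""
    with xopen(path) as handle:
        first = handle.readline()
    if "txStart" in first:
        return read_genes_refgene(path)
    return read_genes_bed12(path)


# -- generic TSV ------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
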