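"""Readers and writers for the on-disk formats the pipeline exchanges.

Conventions: FASTA wrapped at 60 columns; GFF3 1-based inclusive; BED 0-based
half-open. Internally every coordinate is 0-based half-open.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_HEADER = "##gff-version 3"


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a gene-level GFF3 (feature type ``gene``, ``ID=`` attribute)."""
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for row in genes.itertuples(index=False):
            strand = getattr(row, "strand", "+") or "+"
            fh.write(
                f"{row.chrom}\tcnsvar\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                (f[0], int(f[3]) - 1, int(f[4]), f[6], attrs.get("ID", f[8]))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def write_bed(df: pd.DataFrame, path: str | os.PathLike, extra: list[str] | None = None) -> None:
    """Write BED6 (+ optional extra columns present in ``df``)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = getattr(row, "name", None) or getattr(row, "cns_id", None) or "."
            score = getattr(row, "score", 0)
            strand = getattr(row, "strand", ".") or "."
            fields = [row.chrom, row.start, row.end, name, score, strand]
            for c in extra or []:
                fields.append(getattr(row, c))
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_bed(path: str | os.PathLike, extra: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"] + list(extra or [])
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#", dtype={0: str}
    )
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
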