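"""Readers and writers for the on-disk formats used across the pipeline.

FASTA goes through Biopython; tabular formats are plain TSV via pandas.
All genomic coordinates on disk are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNMENT_COLUMNS = [
    "read_id",
    "target_id",
    "target_start",
    "target_end",
    "read_len",
    "aligned_len",
    "pct_identity",
    "sample_id",
    "dataset",
]

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_alignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return df


def write_alignments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ALIGNMENT_COLUMNS)


@dataclass(frozen=True)
class GffGene:
    """One gene row of a GFF3 file (1-based inclusive coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    category: str  # product_class attribute


def _parse_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in field.rstrip(";").split(";"):
        if "=" in chunk:
            key, val = chunk.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_gff(path: str | Path) -> list[GffGene]:
    """Parse gene features from a GFF3 file.

    Only ``gene``/``CDS`` rows are kept; the functional category is carried in
    a ``product_class`` attribute.
    """
    genes: list[GffGene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}")
            if fields[2] not in ("gene", "CDS"):
                continue
            attrs = _parse_attributes(fields[8])
            genes.append(
                GffGene(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}"),
                    contig_id=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                    category=attrs.get("product_class", "other"),
                )
            )
    return genes


def write_gff(genes: Iterable[GffGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};product_class={g.category}"
            fh.write(
                f"{g.contig_id}\tsoilvirome\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
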