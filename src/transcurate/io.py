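"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA/FASTQ go through Bio.SeqIO; tabular homology-hit files use the
12-column BLAST outfmt-6 dialect (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore) via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import Contig

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

OUTFMT6_DTYPES = {
    "qseqid": str, "sseqid": str, "pident": float, "length": int,
    "mismatch": int, "gapopen": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "evalue": float, "bitscore": float,
}


def read_fasta(path: str | Path) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_protein_fasta(proteins: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a 12-column outfmt-6 hit table (no header)."""
    df = pd.read_csv(
        path, sep="\t", names=OUTFMT6_COLUMNS, dtype=OUTFMT6_DTYPES, comment="#"
    )
    return df


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=OUTFMT6_COLUMNS)


def read_fastq(path: str | Path):
    """Yield (read_id, sequence, phred qualities) from a phred+33 FASTQ."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])


def write_fastq(reads, path: str | Path) -> None:
    """Write (read_id, sequence, qualities) triples as phred+33 FASTQ."""
    records = []
    for rid, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_go_annotations(path: str | Path) -> pd.DataFrame:
    """Two-to-four-column gene->GO table: gene_id, term_id[, term_name[, namespace]]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    cols = ["gene_id", "term_id", "term_name", "namespace"][: df.shape[1]]
    df.columns = cols
    return df


def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Three-column domain-hit table: seq_id, domain_accession, evalue."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["seq_id", "domain", "evalue"],
        dtype={"seq_id": str, "domain": str, "evalue": float},
    )
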