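"""FASTA and TSV I/O helpers shared across modules."""

from __future__ import annotations

from typing import Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import binqc


def write_fasta(records: Iterable[Tuple[str, str]], path_or_handle) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    if hasattr(path_or_handle, "write"):
        SeqIO.write(seqs, path_or_handle, "fasta")
    else:
        SeqIO.write(seqs, str(path_or_handle), "fasta")


def read_fasta(path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_proteomes_fasta(path) -> dict:
    """Proteomes keyed by genome from ``genomeID|proteinID`` FASTA headers."""
    proteomes: dict = {}
    for pid, seq in read_fasta(path):
        genome = pid.split("|", 1)[0]
        proteomes.setdefault(genome, []).append((pid, seq))
    return proteomes


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(binqc.GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df["taxon"] = df["taxon"].where(df["taxon"].notna(), None)
    return df


def read_taxonomy_hits(path) -> pd.DataFrame:
    """Gene-vs-database hit table: gene_id, subject_taxon, e_value, similarity,
    coverage, bitscore (optional subject_id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "subject_taxon", "e_value", "similarity", "coverage",
                "bitscore"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy hit table missing columns: {sorted(missing)}")
    if "subject_id" not in df.columns:
        df["subject_id"] = df["subject_taxon"]
    return df


def taxonomy_hits_by_gene(df: pd.DataFrame) -> dict:
    hits: dict = {}
    for row in df.itertuples():
        hits.setdefault(row.gene_id, []).append(binqc.GeneTaxonomyHit(
            gene_id=row.gene_id, subject_taxon=row.subject_taxon,
            e_value=float(row.e_value), similarity=float(row.similarity),
            coverage=float(row.coverage), bitscore=float(row.bitscore),
            subject_id=str(row.subject_id)))
    return hits
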