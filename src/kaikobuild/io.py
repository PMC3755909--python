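"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; GFF3 emission is plain text (1-based,
inclusive, per the GFF3 spec); tables are TSV via pandas.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def write_fasta(path: str, records: Iterable[Tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gff3(path: str, genes: pd.DataFrame, source: str = "kaikobuild") -> None:
    """Write gene/mRNA/exon features from a gene table.

    ``genes`` needs columns gene_id, chrom, strand, exon_starts, exon_ends
    (comma-joined 0-based half-open internal coordinates).  Emitted GFF3 is
    1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            starts = [int(x) for x in str(row.exon_starts).split(",")]
            ends = [int(x) for x in str(row.exon_ends).split(",")]
            g0, g1 = min(starts), max(ends)
            gid = row.gene_id
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{g0 + 1}\t{g1}\t.\t{row.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{row.chrom}\t{source}\tmRNA\t{g0 + 1}\t{g1}\t.\t{row.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(zip(starts, ends), 1):
                fh.write(
                    f"{row.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{row.strand}\t.\t"
                    f"ID={gid}.e{i};Parent={gid}.t1\n"
                )


def read_gff3_exons(path: str) -> pd.DataFrame:
    """Read exon features back into a table of 0-based half-open blocks."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique", keep_order=True)
    rows = []
    for exon in db.features_of_type("exon"):
        parent = list(db.parents(exon, featuretype="mRNA"))
        tid = parent[0].id if parent else (exon.attributes.get("Parent", ["?"])[0])
        rows.append((tid, exon.seqid, exon.strand, exon.start - 1, exon.end))
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "strand", "start", "end"])


def write_tsv(path: str, df: pd.DataFrame) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
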