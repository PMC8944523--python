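"""Reading and writing the standard formats a species bundle is made of.

FASTA goes through Biopython's SeqIO; GFF3 through gffutils with an
in-memory sqlite database.  The GFF3 dialect expected is the common
gene -> mRNA -> exon/CDS hierarchy with ID/Parent attributes, 1-based
inclusive coordinates.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, SpeciesBundle, Transcript


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence} (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff3(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Parse a GFF3 annotation into GeneModel objects keyed by gene id."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = tuple(
                sorted(
                    (f.start, f.end)
                    for f in db.children(mrna, featuretype="exon")
                )
            )
            cds = tuple(
                sorted(
                    (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
                )
            )
            transcripts.append(Transcript(mrna.id, exons, cds))
        transcripts.sort(key=lambda t: t.transcript_id)
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
            transcripts=tuple(transcripts),
        )
    return genes


def read_bundle(
    gff3: str | os.PathLike,
    genome_fasta: str | os.PathLike | None = None,
    cds_fasta: str | os.PathLike | None = None,
    protein_fasta: str | os.PathLike | None = None,
) -> SpeciesBundle:
    """Load a species bundle (annotation plus whichever FASTAs are given)."""
    return SpeciesBundle(
        genes=read_gff3(gff3),
        genome=read_fasta(genome_fasta) if genome_fasta else {},
        cds=read_fasta(cds_fasta) if cds_fasta else {},
        proteins=read_fasta(protein_fasta) if protein_fasta else {},
    )


def write_tsv(rows: Iterable[dict], path: str | os.PathLike, columns: list[str]) -> None:
    """Small, dependency-light TSV writer for stage outputs."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
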