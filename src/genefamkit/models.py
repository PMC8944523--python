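"""Shared domain types: gene models, family members, duplicate pairs.

Coordinates follow the GFF3 convention externally (1-based, inclusive);
all arithmetic helpers state their convention explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted by start
    cds: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted by start

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """One gene locus with its transcripts, as read from a GFF3 file."""

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive
    end: int
    transcripts: tuple[Transcript, ...] = ()

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class DomainHit:
    start: int  # 1-based position in the protein
    end: int
    score: float
    complete: bool


@dataclass
class FamilyMember:
    """An accepted family gene with its assigned name.

    The name follows the convention <3-letter species prefix><3-letter
    family label><chromosome number>.<ordinal>, e.g. GsoGPX2.4 for the 4th
    GPX gene on chromosome 2 of Glycine soja.  Ordinals run 5'->3' by
    ascending start coordinate within each chromosome.
    """

    gene_id: str
    name: str
    species_prefix: str
    family_label: str
    chromosome: str
    strand: str
    start: int
    end: int
    protein: str
    cds: str
    domain_hit: DomainHit
    localization: str | None = None  # imported annotation, never computed


@dataclass
class DuplicatePair:
    member_a: str
    member_b: str
    identity: float  # protein %, global alignment
    duplication_type: str  # 'tandem' | 'segmental' | 'unknown'
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    selection: str | None = None  # 'purifying' | 'neutral' | 'positive' | ...
    time_mya: float | None = None


@dataclass
class SpeciesBundle:
    """In-memory view of one species' input files."""

    genes: dict[str, GeneModel]
    genome: dict[str, str]  # chromosome -> sequence
    cds: dict[str, str]  # transcript id -> CDS sequence
    proteins: dict[str, str]  # transcript id -> protein sequence

    def gene_order(self) -> dict[str, list[str]]:
        """Per-chromosome gene ids sorted by start coordinate."""
        order: dict[str, list[str]] = {}
        for g in sorted(self.genes.values(), key=lambda g: (g.chromosome, g.start)):
            order.setdefault(g.chromosome, []).append(g.gene_id)
        return order


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str  # IUPAC nucleotide codes
    category: str = "other"  # stress / hormone / light / other


@dataclass(frozen=True)
class CisElementHit:
    member: str
    element: str
    position: int  # 1-based start of the match in the promoter window (5'->3')
    strand: str  # '+' or '-' relative to the gene's coding strand
    matched: str  # the window substring at [position, position+len-1]


@dataclass
class GeneStructure:
    member: str
    exon_count: int
    intron_count: int
    segments: list[tuple[str, int, int]] = field(default_factory=list)
    # segment types: 'exon', 'intron', 'CDS', 'UTR'; gene-local 1-based coords
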