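"""Family member identification: filtering criteria and naming convention.

Candidate loci are reduced to one representative transcript each (the
longest CDS), short coding sequences (< 150 bp) are removed, truncated
proteins (internal stop, missing terminal stop) are removed, and the
survivors are scanned for the family's domain signature with an ungapped
position-specific scoring matrix.  Genes whose best domain window is
incomplete — the window does not fit, or the protein is shorter than the
completeness fraction of the model — are discarded.  Accepted members
are named <prefix><family><chromosome>.<ordinal>, ordinals assigned by
ascending start coordinate per chromosome (e.g. GsoGPX2.4 = 4th GPX gene
on chromosome 2 of Glycine soja); genes on unplaced scaffolds get the
pseudo-chromosome token "U".

The PSSM scan stands in for profile-HMM search: the filtering criterion
is a completeness predicate on the domain, not a specific tool's score,
and externally produced domain-hit tables can be imported instead
(`read_domain_hits`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._codon import translate_cds
from .models import DomainHit, FamilyMember, GeneModel, SpeciesBundle

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: invented 40-residue signature used by the synthetic bundles; real runs
#: supply their own model (consensus string or per-position score table)
DEFAULT_DOMAIN_CONSENSUS = "WCNQFGHLVPNIKAFYDEMTGRSWLCEHPKVDAYQINGTR"


@dataclass
class DomainModel:
    """Ungapped per-position scoring model for a protein domain."""

    name: str
    scores: list[dict[str, float]]  # one dict per model position
    threshold: float
    completeness_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.completeness_fraction <= 1:
            raise ValueError("completeness fraction must be in (0, 1]")

    @property
    def length(self) -> int:
        return len(self.scores)

    @property
    def max_score(self) -> float:
        return sum(max(col.values()) for col in self.scores)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        name: str = "domain",
        match: float = 2.0,
        mismatch: float = 0.0,
        threshold_fraction: float = 0.7,
        completeness_fraction: float = 0.8,
    ) -> "DomainModel":
        consensus = consensus.upper()
        scores = [
            {aa: (match if aa == c else mismatch) for aa in AMINO_ACIDS}
            for c in consensus
        ]
        return cls(
            name=name,
            scores=scores,
            threshold=threshold_fraction * match * len(consensus),
            completeness_fraction=completeness_fraction,
        )


def scan_domain(protein: str, model: DomainModel) -> DomainHit | None:
    """Best ungapped window of the model against the protein.

    Returns None when the protein is shorter than the completeness
    fraction of the model length (a truncated protein cannot carry a
    complete domain).  'X' residues score 0 at every position.  The hit
    is flagged complete when a full-length window fits and its score
    reaches the model threshold.
    """
    protein = protein.upper().rstrip("*")
    for aa in protein:
        if aa != "X" and aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {aa!r}")
    L = model.length
    if len(protein) < model.completeness_fraction * L:
        return None
    best: DomainHit | None = None
    if len(protein) >= L:
        for start in range(len(protein) - L + 1):
            score = 0.0
            for k in range(L):
                aa = protein[start + k]
                if aa != "X":
                    score += model.scores[k][aa]
            if best is None or score > best.score:
                best = DomainHit(
                    start=start + 1,
                    end=start + L,
                    score=score,
                    complete=score >= model.threshold,
                )
    else:
        # partial overlap: slide the model prefix over the protein tail
        for start in range(len(protein)):
            span = min(L, len(protein) - start)
            score = 0.0
            for k in range(span):
                aa = protein[start + k]
                if aa != "X":
                    score += model.scores[k][aa]
            if best is None or score > best.score:
                best = DomainHit(start=start + 1, end=start + span, score=score,
                                 complete=False)
    return best


def select_longest_transcript(gene: GeneModel) -> str:
    """The representative transcript: maximum CDS length, ties broken by
    lexicographically smallest transcript id."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return min(gene.transcripts, key=lambda t: (-t.cds_length, t.transcript_id)).transcript_id


def filter_min_cds(records: dict[str, str], min_bp: int = 150) -> dict[str, str]:
    """Retain records whose CDS length is at least ``min_bp`` (inclusive)."""
    return {k: v for k, v in records.items() if len(v) >= min_bp}


def is_truncated(cds: str) -> bool:
    """A CDS is truncated when its frame is broken, its translation has an
    internal stop, or it lacks an in-frame terminal stop."""
    if len(cds) % 3 != 0:
        return True
    try:
        aa = translate_cds(cds)
    except ValueError:
        return True
    return not aa.endswith("*") or "*" in aa[:-1]


_CHROM_NUM = re.compile(r"(\d+)$")


def chromosome_token(chromosome: str) -> str:
    """Numeric token for a placed chromosome, 'U' for unplaced scaffolds."""
    low = chromosome.lower()
    if low.startswith(("chr", "chromosome")) or chromosome.isdigit():
        m = _CHROM_NUM.search(chromosome)
        if m:
            return str(int(m.group(1)))
    return "U"


def assign_names(
    members: list[FamilyMember], species_prefix: str, family_label: str
) -> list[FamilyMember]:
    """Assign <prefix><family><chrom>.<ordinal> names, ordinals by ascending
    start coordinate within each chromosome (1-based)."""
    seen = [m.gene_id for m in members]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate gene ids among members")
    by_chrom: dict[str, list[FamilyMember]] = {}
    for m in members:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom_members in by_chrom.values():
        chrom_members.sort(key=lambda m: m.start)
        token = chromosome_token(chrom_members[0].chromosome)
        for ordinal, m in enumerate(chrom_members, start=1):
            m.species_prefix = species_prefix
            m.family_label = family_label
            m.name = f"{species_prefix}{family_label}{token}.{ordinal}"
    return sorted(members, key=lambda m: (m.chromosome, m.start))


def identify_family(
    bundle: SpeciesBundle,
    model: DomainModel,
    species_prefix: str,
    family_label: str,
    min_cds_bp: int = 150,
    localization: dict[str, str] | None = None,
) -> list[FamilyMember]:
    """Run the full filtering cascade on a species bundle and return named
    family members.

    The three criteria (representative transcript, minimum CDS length,
    complete domain / untruncated protein) commute, so their order does
    not change the surviving set.
    """
    members: list[FamilyMember] = []
    for gene in bundle.genes.values():
        if not gene.transcripts:
            continue
        tid = select_longest_transcript(gene)
        cds = bundle.cds.get(tid)
        if cds is None or len(cds) < min_cds_bp:
            continue
        if is_truncated(cds):
            continue
        protein = bundle.proteins.get(tid) or translate_cds(cds).rstrip("*")
        protein = protein.rstrip("*")
        hit = scan_domain(protein, model)
        if hit is None or not hit.complete:
            continue
        members.append(
            FamilyMember(
                gene_id=gene.gene_id,
                name="",
                species_prefix=species_prefix,
                family_label=family_label,
                chromosome=gene.chromosome,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                protein=protein,
                cds=cds,
                domain_hit=hit,
                localization=(localization or {}).get(gene.gene_id),
            )
        )
    return assign_names(members, species_prefix, family_label)


def read_domain_hits(path: str) -> dict[str, DomainHit]:
    """Import externally produced domain hits (TSV: gene_id, start, end,
    score, complete) as an alternative to the built-in PSSM scan."""
    hits: dict[str, DomainHit] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits[f[idx["gene_id"]]] = DomainHit(
                start=int(f[idx["start"]]),
                end=int(f[idx["end"]]),
                score=float(f[idx["score"]]),
                complete=f[idx["complete"]].lower() in ("1", "true", "yes"),
            )
    return hits
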