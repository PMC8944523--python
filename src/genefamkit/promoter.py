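"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2000 bp immediately upstream of the translation start
site (the first CDS base), reported 5'->3' on the gene's coding strand;
on the minus strand that means the reverse complement of the 2000 bp
3' of the CDS start in genome coordinates.  Windows truncated by a
chromosome end are returned shorter, flagged by a warning.

The element dictionary ships as an editable TSV of IUPAC consensus
strings seeded with commonly scanned plant elements (ABRE, MYB, MBS,
TGACG-motif, ...).  Scanning reports every compatible match on both
strands of the window, overlaps included; reverse-complement element
pairs (TGACG-motif / CGTCA-motif) are kept as distinct names, mirroring
the convention of plant promoter databases.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from ._codon import reverse_complement
from .models import CisElement, CisElementHit, GeneModel

_VALID_IUPAC = set(ambiguous_dna_values)


def load_dictionary(path: str | None = None) -> list[CisElement]:
    """Load the cis-element dictionary (TSV: name, consensus, category).

    Consensus strings must be IUPAC nucleotide codes; anything else fails
    at load time.
    """
    if path is None:
        ref = resources.files("genefamkit.data").joinpath("plantcare_elements.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    elements = []
    for row in df.itertuples(index=False):
        consensus = str(row.consensus).upper()
        bad = set(consensus) - _VALID_IUPAC
        if bad:
            raise ValueError(
                f"element {row.name!r}: invalid IUPAC code(s) {sorted(bad)}"
            )
        category = getattr(row, "category", "other")
        elements.append(CisElement(str(row.name), consensus, str(category)))
    return elements


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for c in consensus:
        opts = ambiguous_dna_values[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def cds_start_genomic(gene: GeneModel, transcript_id: str | None = None) -> int:
    """Genomic coordinate (1-based) of the translation start site."""
    t = gene.transcript(transcript_id) if transcript_id else gene.transcripts[0]
    if not t.cds:
        raise ValueError(f"gene {gene.gene_id} has no CDS")
    cds = sorted(t.cds)
    return cds[0][0] if gene.strand == "+" else cds[-1][1]


def extract_promoter(
    genome: dict[str, str],
    gene: GeneModel,
    length: int = 2000,
    transcript_id: str | None = None,
) -> str:
    """The ``length`` bp upstream of the translation start, 5'->3' on the
    gene's coding strand; truncated with a warning at chromosome ends."""
    if gene.chromosome not in genome:
        raise ValueError(f"chromosome {gene.chromosome} absent from genome")
    chrom = genome[gene.chromosome]
    start_pos = cds_start_genomic(gene, transcript_id)
    if gene.strand == "+":
        lo = max(1, start_pos - length)
        window = chrom[lo - 1 : start_pos - 1]
    else:
        hi = min(len(chrom), start_pos + length)
        window = reverse_complement(chrom[start_pos : hi])
    if len(window) < length:
        warnings.warn(
            f"promoter of {gene.gene_id} truncated to {len(window)} bp by the "
            f"chromosome end",
            stacklevel=2,
        )
    return window


def scan_cis_elements(
    promoter: str,
    dictionary: list[CisElement],
    member: str = "",
    both_strands: bool = True,
) -> list[CisElementHit]:
    """All matches of every dictionary element in the window.

    Positions are 1-based starts on the window (5'->3' coding strand);
    reverse-strand matches are reported at the leftmost window position
    they cover, with strand '-'.  Overlapping hits are all reported.
    """
    promoter = promoter.upper()
    hits: list[CisElementHit] = []
    for element in dictionary:
        pattern = _iupac_regex(element.consensus)
        k = len(element.consensus)
        for m in _finditer_overlapping(pattern, promoter):
            hits.append(CisElementHit(member, element.name, m + 1, "+",
                                      promoter[m : m + k]))
        if both_strands:
            rc = reverse_complement(promoter)
            for m in _finditer_overlapping(pattern, rc):
                pos = len(promoter) - (m + k) + 1
                hits.append(CisElementHit(member, element.name, pos, "-",
                                          promoter[pos - 1 : pos - 1 + k]))
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def _finditer_overlapping(pattern: re.Pattern, text: str) -> list[int]:
    out, pos = [], 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            return out
        out.append(m.start())
        pos = m.start() + 1


def element_count_matrix(
    hits: list[CisElementHit],
    members: list[str],
    elements: list[str] | None = None,
    min_total: int | None = None,
) -> pd.DataFrame:
    """Gene x element hit-count matrix (zero-filled).

    ``min_total`` keeps only elements whose total count across members
    exceeds it — the "more than N occurrences" column selection used for
    overview figures.
    """
    if elements is None:
        elements = sorted({h.element for h in hits})
    df = pd.DataFrame(0, index=list(members), columns=list(elements), dtype=int)
    for h in hits:
        if h.member in df.index and h.element in df.columns:
            df.loc[h.member, h.element] += 1
    if min_total is not None:
        df = df.loc[:, df.sum(axis=0) > min_total]
    return df
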