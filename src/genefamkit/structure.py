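"""Exon–intron structure summaries for representative transcripts.

Introns are the gaps between consecutive exons on the coding strand;
UTR segments are exon intervals minus CDS intervals.  Segment
coordinates are reported gene-local (1-based, 5'->3' on the coding
strand) so structures on the two strands are directly comparable.
"""

from __future__ import annotations

from .models import GeneModel, GeneStructure, Transcript


def _to_local(iv: tuple[int, int], gene: GeneModel) -> tuple[int, int]:
    s, e = iv
    if gene.strand == "+":
        return s - gene.start + 1, e - gene.start + 1
    return gene.end - e + 1, gene.end - s + 1


def structure_summary(gene: GeneModel, transcript: Transcript | str) -> GeneStructure:
    if isinstance(transcript, str):
        transcript = gene.transcript(transcript)
    exons = sorted(transcript.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping exons in {gene.gene_id}: "
                             f"({s1},{e1}) and ({s2},{e2})")
    cds = sorted(transcript.cds)
    segments: list[tuple[str, int, int]] = []
    for (s, e) in exons:
        segments.append(("exon", *_to_local((s, e), gene)))
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        segments.append(("intron", *_to_local((e1 + 1, s2 - 1), gene)))
    for (s, e) in cds:
        segments.append(("CDS", *_to_local((s, e), gene)))
    # UTR = exon minus CDS, genomic coordinates, then mapped gene-local
    for (s, e) in exons:
        cover = [(max(s, cs), min(e, ce)) for cs, ce in cds if cs <= e and ce >= s]
        pos = s
        for cs, ce in sorted(cover):
            if pos < cs:
                segments.append(("UTR", *_to_local((pos, cs - 1), gene)))
            pos = ce + 1
        if pos <= e:
            segments.append(("UTR", *_to_local((pos, e), gene)))
    segments.sort(key=lambda t: (t[1], t[2], t[0]))
    return GeneStructure(
        member=gene.gene_id,
        exon_count=len(exons),
        intron_count=len(exons) - 1,
        segments=segments,
    )
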