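"""Codon-level helpers shared by the evolution and simulation modules.

The genetic code is taken from the standard (NCBI table 1) code via
Biopython; everything here is precomputed into plain dicts so the hot
loops (per-codon Ka/Ks counting, mutation planting) stay cheap.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    GENETIC_CODE[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)

#: amino acid -> tuple of codons encoding it (sense codons only)
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    CODONS_FOR_AA.setdefault(GENETIC_CODE[_codon], tuple())
    CODONS_FOR_AA[GENETIC_CODE[_codon]] += (_codon,)

STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard.stop_codons))


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) codon-by-codon, '*' for stops."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in GENETIC_CODE:
            raise ValueError(f"unrecognised codon {codon!r} at position {i}")
        aas.append(GENETIC_CODE[codon])
    return "".join(aas)


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 possible single-nucleotide changes at ``pos`` that
    are synonymous.  Changes creating a stop codon count as nonsynonymous,
    the common convention for Nei–Gojobori site counting."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for nt in NUCLEOTIDES:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if GENETIC_CODE[alt] == aa:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon (sums to 3)."""
    s = sum(synonymous_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) differences between two sense
    codons, averaged over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (possible only for 2-3 difference codons) all pathways are used.
    Equal pathway weights are applied.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        sd = nd = 0.0
        cur = c1
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]
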