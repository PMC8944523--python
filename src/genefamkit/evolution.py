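"""Duplicate-pair detection, tandem/segmental classification, Nei–Gojobori
Ka/Ks, selection inference, divergence dating and synteny links.

The Ka/Ks estimator is the Nei–Gojobori (1986) counting method: potential
synonymous (S) and nonsynonymous (N) sites are each position's synonymous
fraction among the three alternative nucleotides, averaged over the two
sequences; observed differences are partitioned by averaging over all
minimal mutational pathways between differing codons with equal weights,
excluding pathways through stop codons; the resulting proportions are
corrected for multiple hits with Jukes–Cantor, d = -(3/4)ln(1 - (4/3)p).

Selection classes use a narrow neutral band around Ka/Ks = 1 (default
[0.95, 1.05]): ratios below are purifying, above are positive.  Ks = 0
with Ka > 0 leaves the ratio undefined; such pairs are labelled
purifying and flagged degenerate (no synonymous divergence to date).
Divergence times follow T = Ks / (2 lambda) with lambda the per-year
synonymous substitution rate (6.1e-9 for soybean by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import (
    codon_site_counts,
    pathway_differences,
    translate_cds,
)
from .models import DuplicatePair, FamilyMember, SpeciesBundle
from .phylo import global_align

SOYBEAN_LAMBDA = 6.1e-9


# ---------------------------------------------------------------------------
# duplicate detection and classification


def detect_duplicates(
    members: list[FamilyMember], identity_threshold: float = 90.0
) -> list[DuplicatePair]:
    """All unordered member pairs whose global protein identity is strictly
    greater than the threshold (default >90%)."""
    pairs: list[DuplicatePair] = []
    for a, b in itertools.combinations(members, 2):
        _, _, ident = global_align(a.protein, b.protein)
        if ident > identity_threshold:
            pairs.append(DuplicatePair(a.name, b.name, round(ident, 3), "unknown"))
    return pairs


def classify_duplication(
    member_a: FamilyMember,
    member_b: FamilyMember,
    gene_order: dict[str, list[str]],
    max_intervening: int = 5,
) -> str:
    """'tandem' when both genes sit on the same chromosome with at most
    ``max_intervening`` annotated genes between them, else 'segmental';
    'unknown' when either gene is absent from the gene order."""
    ca, cb = member_a.chromosome, member_b.chromosome
    if ca not in gene_order or cb not in gene_order:
        return "unknown"
    if ca != cb:
        return "segmental"
    order = gene_order[ca]
    try:
        ia, ib = order.index(member_a.gene_id), order.index(member_b.gene_id)
    except ValueError:
        return "unknown"
    intervening = abs(ia - ib) - 1
    return "tandem" if intervening <= max_intervening else "segmental"


# ---------------------------------------------------------------------------
# codon alignment and NG86


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Protein-guided codon alignment.

    The two proteins are globally aligned and the gaps propagated back to
    codons; the returned list holds codon columns, gap columns included as
    '---' (they are skipped by the difference counting)."""
    aa_a, aa_b = translate_cds(cds_a), translate_cds(cds_b)
    for name, aa in (("first", aa_a), ("second", aa_b)):
        if "*" in aa[:-1]:
            raise ValueError(f"{name} CDS has an internal stop codon")
    aa_a, aa_b = aa_a.rstrip("*"), aa_b.rstrip("*")
    row_a, row_b, _ = global_align(aa_a, aa_b)
    cols: list[tuple[str, str]] = []
    i = j = 0
    for x, y in zip(row_a, row_b):
        ca = cds_a[3 * i : 3 * i + 3] if x != "-" else "---"
        cb = cds_b[3 * j : 3 * j + 3] if y != "-" else "---"
        if x != "-":
            i += 1
        if y != "-":
            j += 1
        cols.append((ca, cb))
    return cols


@dataclass(frozen=True)
class Ng86Counts:
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float

    @property
    def ps(self) -> float:
        return self.s_diffs / self.s_sites if self.s_sites else 0.0

    @property
    def pn(self) -> float:
        return self.n_diffs / self.n_sites if self.n_sites else 0.0


def ng86_counts(codon_alignment: list[tuple[str, str]]) -> Ng86Counts:
    """Raw NG86 site and difference counts over comparable (gap-free)
    codon columns."""
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    compared = 0
    for ca, cb in codon_alignment:
        if "-" in ca or "-" in cb:
            continue
        compared += 1
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        s_diffs += sd
        n_diffs += nd
    if compared == 0:
        raise ValueError("no comparable codon columns")
    return Ng86Counts(s_sites, n_sites, s_diffs, n_diffs)


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); undefined at p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(codon_alignment: list[tuple[str, str]]) -> tuple[float, float]:
    """(Ka, Ks) by NG86 counting with Jukes–Cantor correction."""
    c = ng86_counts(codon_alignment)
    return jukes_cantor(c.pn), jukes_cantor(c.ps)


# ---------------------------------------------------------------------------
# selection and dating


def classify_selection(
    ka: float, ks: float, neutral_band: tuple[float, float] = (0.95, 1.05)
) -> tuple[str, float | None]:
    """Selection class from Ka and Ks (or from a precomputed ratio by
    passing ks=1.0 and the ratio as ka).

    Returns (class, ratio); the ratio is None for the degenerate Ks = 0
    cases (labelled 'purifying' when Ka > 0 — divergence with no
    synonymous change — and 'identical' when both are 0).
    """
    if ka < 0 or ks < 0:
        raise ValueError("rates must be non-negative")
    if ks == 0.0:
        return ("identical", None) if ka == 0.0 else ("purifying", None)
    r = ka / ks
    lo, hi = neutral_band
    if r < lo:
        return "purifying", r
    if r > hi:
        return "positive", r
    return "neutral", r


def divergence_time(ks: float, lam: float = SOYBEAN_LAMBDA) -> float:
    """T = Ks / (2 lambda), in millions of years (unrounded; round to two
    decimals for reporting)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * lam) / 1.0e6


def analyze_pair(
    member_a: FamilyMember,
    member_b: FamilyMember,
    gene_order: dict[str, list[str]],
    lam: float = SOYBEAN_LAMBDA,
    neutral_band: tuple[float, float] = (0.95, 1.05),
    identity: float | None = None,
) -> DuplicatePair:
    """Full per-pair evolution report: type, Ka, Ks, ratio, class, time."""
    if identity is None:
        identity = global_align(member_a.protein, member_b.protein)[2]
    dup_type = classify_duplication(member_a, member_b, gene_order)
    aln = codon_align(member_a.cds, member_b.cds)
    ka, ks = ng86_ka_ks(aln)
    selection, ratio = classify_selection(ka, ks, neutral_band)
    return DuplicatePair(
        member_a=member_a.name,
        member_b=member_b.name,
        identity=round(identity, 3),
        duplication_type=dup_type,
        ka=ka,
        ks=ks,
        ka_ks=ratio,
        selection=selection,
        time_mya=round(divergence_time(ks, lam), 2),
    )


def analyze_duplicates(
    members: list[FamilyMember],
    bundle: SpeciesBundle,
    identity_threshold: float = 90.0,
    lam: float = SOYBEAN_LAMBDA,
    neutral_band: tuple[float, float] = (0.95, 1.05),
) -> list[DuplicatePair]:
    by_name = {m.name: m for m in members}
    order = bundle.gene_order()
    out = []
    for cand in detect_duplicates(members, identity_threshold):
        a, b = by_name[cand.member_a], by_name[cand.member_b]
        out.append(analyze_pair(a, b, order, lam, neutral_band, cand.identity))
    return out


# ---------------------------------------------------------------------------
# synteny links


@dataclass(frozen=True)
class SyntenyLink:
    query: str
    subject: str
    identity: float
    bin: str  # '<=50' | '<=70' | '<=90' | '>90'
    e_value: float


def identity_bin(identity: float) -> str:
    if identity > 90:
        return ">90"
    if identity > 70:
        return "<=90"
    if identity > 50:
        return "<=70"
    return "<=50"


class _ScoreNull:
    """Extreme-value model for global alignment scores of unrelated
    sequences, fitted on shuffled-sequence pairs at startup.  The E-value
    of an observed score is the expected number of comparisons in the
    search space reaching it under this null."""

    def __init__(self, queries: dict[str, str], subjects: dict[str, str],
                 n_shuffles: int = 60, seed: int = 0):
        rng = np.random.default_rng(seed)
        qnames = sorted(queries)
        snames = sorted(subjects)
        scores = []
        for _ in range(n_shuffles):
            q = queries[qnames[rng.integers(len(qnames))]]
            s = subjects[snames[rng.integers(len(snames))]]
            qs = "".join(rng.permutation(list(q)))
            ss = "".join(rng.permutation(list(s)))
            scores.append(_alignment_score(qs, ss))
        self.loc, self.scale = _fit_gumbel(np.asarray(scores, dtype=float))
        self.n_comparisons = len(queries) * len(subjects)

    def e_value(self, score: float) -> float:
        p = stats.gumbel_r.sf(score, loc=self.loc, scale=self.scale)
        return self.n_comparisons * p


def _fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    # method-of-moments start is stable for the small null samples used here
    scale = scores.std(ddof=1) * math.sqrt(6.0) / math.pi
    loc = scores.mean() - 0.5772156649 * scale
    return loc, max(scale, 1e-6)


def _alignment_score(a: str, b: str) -> float:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return float(aligner.score(a, b))


def synteny_links(
    queries: dict[str, str],
    subjects: dict[str, str],
    e_value_max: float = 1e-10,
    seed: int = 0,
) -> list[SyntenyLink]:
    """All-vs-all protein links significant under the shuffled-sequence
    score null, binned by percent identity (<=50 / <=70 / <=90 / >90)."""
    null = _ScoreNull(queries, subjects, seed=seed)
    links = []
    for qname, q in queries.items():
        for sname, s in subjects.items():
            if qname == sname:
                continue
            _, _, ident = global_align(q, s)
            e = null.e_value(_alignment_score(q, s))
            if e <= e_value_max:
                links.append(SyntenyLink(qname, sname, round(ident, 3),
                                         identity_bin(ident), e))
    return links


# ---------------------------------------------------------------------------
# published reference table


def load_published_pairs() -> pd.DataFrame:
    """Published Ka/Ks/divergence table for the duplicated soybean SOD and
    GPX paralog pairs (G. max and G. soja), used as an input for
    re-deriving selection classes and divergence times."""
    ref = resources.files("genefamkit.data").joinpath("soybean_sod_gpx_duplicates.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
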