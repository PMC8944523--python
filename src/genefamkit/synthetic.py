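"""Synthetic species bundles with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: multi-isoform loci, short/truncated decoy coding sequences,
family members carrying a shared domain signature, tandem and segmental
duplicate pairs evolved at controlled synonymous/nonsynonymous
divergence, promoters with planted cis-elements, tissue-specific
expression effects, and qPCR Ct tables with group effects and replicate
noise.  It makes no attempt at realistic genome composition (repeats,
isochores, GC structure): intergenic sequence is i.i.d. uniform, which
keeps cis-element false-positive rates quantifiable, and planted
promoters overwrite their upstream windows.

Everything is driven by a single seeded generator, so a fixed seed gives
byte-identical output bundles.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import (
    CODONS_FOR_AA,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
    synonymous_fraction,
    translate_cds,
)
from .identify import AMINO_ACIDS, DEFAULT_DOMAIN_CONSENSUS
from .io import write_fasta
from .models import GeneModel, SpeciesBundle, Transcript
from .promoter import load_dictionary

DEFAULT_TISSUES = (
    "root", "stem", "leaf", "flower", "pod", "seed",
    "nodule", "shoot_meristem", "cotyledon", "seedling",
)
DEFAULT_TREATMENTS = ("H2O2", "NaCl", "PEG")
DEFAULT_TIMEPOINTS = (0, 3, 6, 12)
REFERENCE_GENE = "GsoActin-11"


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 6
    chromosome_length: int = 120_000
    n_family_genes: int = 8
    n_decoy_genes: int = 8
    n_multi_isoform_loci: int = 2
    n_short_cds_decoys: int = 2
    #: (target_ks, target_ka) per planted pair
    tandem_pairs: list[tuple[float, float]] = field(default_factory=lambda: [(0.05, 0.01)])
    segmental_pairs: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.05, 0.01), (0.10, 0.02)]
    )
    domain_consensus: str = DEFAULT_DOMAIN_CONSENSUS
    promoter_elements_planted: list[tuple[str, int]] = field(
        default_factory=lambda: [("ABRE", 3), ("TGACG-motif", 2)]
    )
    promoter_length: int = 2000
    #: per-residue substitution rate outside the domain, relative to the
    #: family template.  0.18 puts non-pair members at ~76% mean pairwise
    #: identity: far above the 50% homology filter, and ~5 sd below the
    #: >90% duplicate threshold, so only planted pairs are ever detected
    family_mutation_rate: float = 0.18

    def validate(self) -> None:
        for ks, ka in self.tandem_pairs + self.segmental_pairs:
            if ks < 0 or ka < 0:
                raise ValueError("target Ks and Ka must be non-negative")
        n_pair_genes = 2 * (len(self.tandem_pairs) + len(self.segmental_pairs))
        if n_pair_genes > self.n_family_genes:
            raise ValueError(
                f"{n_pair_genes} genes needed for the planted pairs but only "
                f"{self.n_family_genes} family genes configured"
            )
        if self.segmental_pairs and self.n_chromosomes < 2:
            raise ValueError("segmental pairs need at least 2 chromosomes")
        if self.chromosome_length < 2 * self.promoter_length + 3000:
            raise ValueError("chromosomes too short to hold genes with promoter flanks")


@dataclass
class GroundTruth:
    family_gene_ids: list[str] = field(default_factory=list)
    #: dicts with gene_a, gene_b, type, target_ks, target_ka
    duplicate_pairs: list[dict] = field(default_factory=list)
    #: gene id -> [(element name, 1-based window position, strand)]
    cis_elements: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    domain_consensus: str = ""
    expression_effects: dict | None = None
    qpcr_effects: dict | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "family_gene_ids": self.family_gene_ids,
            "duplicate_pairs": self.duplicate_pairs,
            "cis_elements": {
                g: [[e, p, s] for e, p, s in hits]
                for g, hits in self.cis_elements.items()
            },
            "domain_consensus": self.domain_consensus,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    aas = np.array(list(AMINO_ACIDS))
    return "M" + "".join(aas[rng.integers(0, 20, size=n - 1)])


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [CODONS_FOR_AA[aa][rng.integers(0, len(CODONS_FOR_AA[aa]))] for aa in protein]
    codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    return "".join(codons)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random sense codons + stop."""
    body = [SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))] for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + STOP_CODONS[rng.integers(0, len(STOP_CODONS))]


def _inverse_jc(d: float) -> float:
    if not (d >= 0 and math.isfinite(d)):
        raise ValueError(f"target rate {d!r} must be finite and non-negative")
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if p >= 0.75:
        raise ValueError(
            f"target {d} implies a proportion of differences >= 3/4, outside the "
            f"Jukes-Cantor domain"
        )
    return p


def evolve_duplicate(
    cds: str,
    target_ks: float,
    target_ka: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Mutate a CDS so the expected NG86 (Ks, Ka) between input and output
    equal the targets.

    The target rates are Jukes–Cantor-inverted to proportions pS, pN; each
    codon then receives at most one substitution, synonymous with
    probability pS x (its synonymous sites) and nonsynonymous with
    probability pN x (its nonsynonymous sites), the position chosen
    proportionally to its per-position fraction.  One hit per codon keeps
    the NG86 difference counting free of mutational-pathway ambiguity, so
    the expected estimates equal the targets exactly (multiple hits are
    represented through the Jukes–Cantor transform rather than simulated).
    Stop codons are never introduced and the frame is preserved.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    aa = translate_cds(cds)
    if "*" in aa[:-1]:
        raise ValueError("CDS has internal stop codons")
    ps = _inverse_jc(target_ks)
    pn = _inverse_jc(target_ka)
    out: list[str] = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if GENETIC_CODE[codon] == "*":  # terminal stop: left untouched
            out.append(codon)
            continue
        f = [synonymous_fraction(codon, pos) for pos in range(3)]
        lam_s = ps * sum(f)
        lam_n = pn * (3.0 - sum(f))
        if lam_s + lam_n > 1.0:
            raise ValueError(
                "target divergences too large for the one-hit-per-codon scheme"
            )
        u = rng.random()
        if u < lam_s + lam_n:
            want_syn = u < lam_s
            weights = f if want_syn else [1.0 - x for x in f]
            total = sum(weights)
            r = rng.random() * total
            pos = 0
            while r > weights[pos]:
                r -= weights[pos]
                pos += 1
            alts = []
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if GENETIC_CODE[alt] == "*":
                    continue
                if (GENETIC_CODE[alt] == GENETIC_CODE[codon]) == want_syn:
                    alts.append(alt)
            if alts:
                codon = alts[rng.integers(0, len(alts))]
        out.append(codon)
    return "".join(out)


# ---------------------------------------------------------------------------
# locus construction


@dataclass
class _TranscriptSpec:
    transcript_id: str
    exons: list[tuple[int, int]]  # local, 1-based, coding orientation
    cds: list[tuple[int, int]]
    cds_seq: str


@dataclass
class _Locus:
    gene_id: str
    kind: str  # 'family' | 'decoy' | 'multi' | 'short'
    seq_local: str  # coding-orientation region sequence
    transcripts: list[_TranscriptSpec]
    cds_start_local: int  # 1-based translation start in the local region


def _split_lengths(rng: np.random.Generator, total: int, parts: int,
                   multiple_of: int = 1, minimum: int = 6) -> list[int]:
    if parts == 1:
        return [total]
    units = total // multiple_of
    min_units = max(1, minimum // multiple_of)
    while True:
        cuts = sorted(rng.choice(np.arange(1, units), size=parts - 1, replace=False))
        lens = np.diff([0, *cuts, units]) * multiple_of
        if all(l >= min_units * multiple_of for l in lens):
            return [int(l) for l in lens]


def _build_single_isoform(rng: np.random.Generator, gene_id: str, kind: str,
                          cds: str, n_exons: int) -> _Locus:
    chunks = _split_lengths(rng, len(cds), n_exons)
    u5 = int(rng.integers(20, 81))
    u3 = int(rng.integers(20, 81))
    introns = [int(rng.integers(80, 251)) for _ in range(n_exons - 1)]
    seq_parts = [_random_dna(rng, u5)]
    exons: list[tuple[int, int]] = []
    cds_iv: list[tuple[int, int]] = []
    pos = u5
    offset = 0
    for k, chunk_len in enumerate(chunks):
        chunk = cds[offset : offset + chunk_len]
        offset += chunk_len
        exon_start = pos + 1 if k > 0 else 1
        seq_parts.append(chunk)
        cds_iv.append((pos + 1, pos + chunk_len))
        pos += chunk_len
        if k == n_exons - 1:
            seq_parts.append(_random_dna(rng, u3))
            exons.append((exon_start, pos + u3))
            pos += u3
        else:
            exons.append((exon_start, pos))
            intron = _random_dna(rng, introns[k])
            seq_parts.append(intron)
            pos += introns[k]
    spec = _TranscriptSpec(f"{gene_id}.t1", exons, cds_iv, cds)
    return _Locus(gene_id, kind, "".join(seq_parts), [spec], u5 + 1)


def _build_multi_isoform(rng: np.random.Generator, gene_id: str) -> _Locus:
    n_codons = int(rng.integers(60, 100))
    cds = _random_cds(rng, n_codons)
    chunks = _split_lengths(rng, len(cds), 3, multiple_of=3, minimum=30)
    u5, u3 = int(rng.integers(20, 81)), int(rng.integers(20, 81))
    i1, i2 = int(rng.integers(80, 251)), int(rng.integers(80, 251))
    c1 = cds[: chunks[0]]
    c2 = cds[chunks[0] : chunks[0] + chunks[1]]
    c3 = cds[chunks[0] + chunks[1] :]
    seq = _random_dna(rng, u5) + c1 + _random_dna(rng, i1) + c2 + \
        _random_dna(rng, i2) + c3 + _random_dna(rng, u3)
    e1 = (1, u5 + len(c1))
    e2 = (e1[1] + i1 + 1, e1[1] + i1 + len(c2))
    e3 = (e2[1] + i2 + 1, e2[1] + i2 + len(c3) + u3)
    cds1 = (u5 + 1, u5 + len(c1))
    cds2 = (e2[0], e2[1])
    cds3 = (e3[0], e3[0] + len(c3) - 1)
    t1 = _TranscriptSpec(f"{gene_id}.t1", [e1, e2, e3], [cds1, cds2, cds3], cds)
    t2 = _TranscriptSpec(f"{gene_id}.t2", [e1, e3], [cds1, cds3], c1 + c3)
    return _Locus(gene_id, "multi", seq, [t1, t2], u5 + 1)


# ---------------------------------------------------------------------------
# promoter planting


def _iupac_pattern(consensus: str) -> re.Pattern:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return re.compile(
        "".join(
            o if len(o) == 1 else f"[{o}]"
            for o in (ambiguous_dna_values[c] for c in consensus)
        )
    )


def _instantiate(rng: np.random.Generator, consensus: str) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(
        opts[rng.integers(0, len(opts))]
        for opts in (ambiguous_dna_values[c] for c in consensus)
    )


def _all_match_spans(pattern: re.Pattern, text: str, k: int) -> list[tuple[int, int]]:
    spans, pos = [], 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            return spans
        spans.append((m.start(), m.start() + k))
        pos = m.start() + 1


def _plant_promoter(
    rng: np.random.Generator,
    length: int,
    planted: list[tuple[str, int]],
    consensi: dict[str, str],
) -> tuple[str, list[tuple[str, int, str]]]:
    """Random window carrying exactly the requested element copies.

    Accidental matches of the planted element names (either strand) are
    scrubbed by redrawing unprotected bases, so downstream scans count
    exactly the planted copies for those elements.
    """
    window = list(_random_dna(rng, length))
    protected = np.zeros(length, dtype=bool)
    placements: list[tuple[str, int, str]] = []
    # margin keeps planted spans apart so any motif created across a span
    # junction still contains redrawable (unprotected) bases
    margin = max(len(consensi[name]) for name, _ in planted)
    for name, count in planted:
        consensus = consensi[name]
        k = len(consensus)
        for _ in range(count):
            for _attempt in range(1000):
                start = int(rng.integers(0, length - k + 1))
                lo = max(0, start - margin)
                hi = min(length, start + k + margin)
                if not protected[lo:hi].any():
                    break
            else:
                raise RuntimeError("could not place promoter element")
            window[start : start + k] = list(_instantiate(rng, consensus))
            protected[start : start + k] = True
            placements.append((name, start + 1, "+"))
    patterns = {name: _iupac_pattern(consensi[name]) for name, _ in planted}
    lens = {name: len(consensi[name]) for name, _ in planted}
    expected = {
        name: {(p - 1, p - 1 + lens[name]) for n2, p, _ in placements if n2 == name}
        for name in patterns
    }
    for _ in range(500):
        text = "".join(window)
        rc = reverse_complement(text)
        accidental: tuple[int, int] | None = None
        for name, pat in patterns.items():
            k = lens[name]
            fwd = set(_all_match_spans(pat, text, k))
            rev = {
                (length - e, length - s) for s, e in _all_match_spans(pat, rc, k)
            }
            extras = (fwd - expected[name]) | rev
            if extras:
                accidental = sorted(extras)[0]
                break
        if accidental is None:
            return "".join(window), placements
        s, e = accidental
        if protected[s:e].all():
            raise ValueError(
                "planted elements conflict: one planted instance contains a "
                "match of another planted element and cannot be scrubbed"
            )
        for i in range(s, e):
            if not protected[i]:
                window[i] = "ACGT"[rng.integers(0, 4)]
    raise RuntimeError("promoter scrubbing did not converge")


# ---------------------------------------------------------------------------
# bundle generation


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    gff3: str
    cds: dict[str, str]
    proteins: dict[str, str]
    truth: GroundTruth

    def to_species_bundle(self) -> SpeciesBundle:
        genes = _gene_models_from_gff(self.gff3)
        return SpeciesBundle(genes=genes, genome=self.genome, cds=self.cds,
                             proteins=self.proteins)

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "gff3": os.path.join(out_dir, "annotation.gff3"),
            "cds": os.path.join(out_dir, "cds.fa"),
            "proteins": os.path.join(out_dir, "proteins.fa"),
            "truth": os.path.join(out_dir, "ground_truth.json"),
        }
        write_fasta(self.genome, paths["genome"])
        with open(paths["gff3"], "w") as fh:
            fh.write(self.gff3)
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.proteins, paths["proteins"])
        self.truth.to_json(paths["truth"])
        return paths


def _gene_models_from_gff(gff3: str) -> dict[str, GeneModel]:
    """Parse the generator's own GFF3 text (used for the in-memory view;
    file-based runs go through io.read_gff3)."""
    genes: dict[str, GeneModel] = {}
    mrnas: dict[str, dict] = {}
    for line in gff3.splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        if ftype == "gene":
            genes[a["ID"]] = dict(chromosome=chrom, strand=strand,
                                  start=int(start), end=int(end), transcripts=[])
        elif ftype == "mRNA":
            mrnas[a["ID"]] = dict(gene=a["Parent"], exons=[], cds=[])
        elif ftype in ("exon", "CDS"):
            key = "exons" if ftype == "exon" else "cds"
            mrnas[a["Parent"]][key].append((int(start), int(end)))
    out: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        ts = [
            Transcript(tid, tuple(sorted(m["exons"])), tuple(sorted(m["cds"])))
            for tid, m in mrnas.items()
            if m["gene"] == gid
        ]
        ts.sort(key=lambda t: t.transcript_id)
        out[gid] = GeneModel(gid, g["chromosome"], g["strand"], g["start"],
                             g["end"], tuple(ts))
    return out


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one species bundle plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(domain_consensus=config.domain_consensus)

    # --- family proteins: shared template, member-specific substitutions
    template_len = 180
    dom = config.domain_consensus
    dom_start = 60
    template = (
        _random_protein(rng, dom_start)
        + dom
        + "".join(
            np.array(list(AMINO_ACIDS))[
                rng.integers(0, 20, size=template_len - dom_start - len(dom))
            ]
        )
    )

    def family_protein() -> str:
        prot = list(template)
        for i in range(1, len(prot)):
            if dom_start <= i < dom_start + len(dom):
                continue
            if rng.random() < config.family_mutation_rate:
                prot[i] = AMINO_ACIDS[rng.integers(0, 20)]
        return "".join(prot)

    # --- build loci
    loci: list[_Locus] = []
    gene_counter = 0

    def next_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:03d}"

    pair_plan = [("tandem", ks, ka) for ks, ka in config.tandem_pairs] + [
        ("segmental", ks, ka) for ks, ka in config.segmental_pairs
    ]
    pair_loci: list[tuple[str, _Locus, _Locus]] = []
    n_singles = config.n_family_genes - 2 * len(pair_plan)
    for dup_type, ks, ka in pair_plan:
        cds_a = _back_translate(rng, family_protein())
        cds_b = evolve_duplicate(cds_a, ks, ka, rng=rng)
        la = _build_single_isoform(rng, next_id(), "family", cds_a,
                                   int(rng.integers(6, 9)))
        lb = _build_single_isoform(rng, next_id(), "family", cds_b,
                                   int(rng.integers(6, 9)))
        pair_loci.append((dup_type, la, lb))
        truth.duplicate_pairs.append(
            dict(gene_a=la.gene_id, gene_b=lb.gene_id, type=dup_type,
                 target_ks=ks, target_ka=ka)
        )
        truth.family_gene_ids += [la.gene_id, lb.gene_id]
    single_family = []
    for _ in range(n_singles):
        locus = _build_single_isoform(rng, next_id(), "family",
                                      _back_translate(rng, family_protein()),
                                      int(rng.integers(6, 9)))
        single_family.append(locus)
        truth.family_gene_ids.append(locus.gene_id)
    decoys = [
        _build_single_isoform(
            rng, next_id(), "decoy",
            _back_translate(rng, _random_protein(rng, int(rng.integers(120, 221)))),
            int(rng.integers(1, 5)),
        )
        for _ in range(config.n_decoy_genes)
    ]
    multis = [_build_multi_isoform(rng, next_id()) for _ in range(config.n_multi_isoform_loci)]
    shorts = [
        _build_single_isoform(rng, next_id(), "short",
                              _random_cds(rng, int(rng.integers(12, 42))), 1)
        for _ in range(config.n_short_cds_decoys)
    ]

    # --- distribute across chromosomes; tandem blocks stay contiguous
    decoy_pool = list(decoys)
    chrom_items: list[list[list[_Locus]]] = [[] for _ in range(config.n_chromosomes)]
    chrom_cycle = 0
    for dup_type, la, lb in pair_loci:
        if dup_type == "tandem":
            block = [la]
            n_between = int(rng.integers(0, 3))
            for _ in range(min(n_between, len(decoy_pool))):
                block.append(decoy_pool.pop())
            block.append(lb)
            chrom_items[chrom_cycle % config.n_chromosomes].append(block)
            chrom_cycle += 1
        else:
            ca = chrom_cycle % config.n_chromosomes
            cb = (chrom_cycle + 1) % config.n_chromosomes
            chrom_items[ca].append([la])
            chrom_items[cb].append([lb])
            chrom_cycle += 2
    for locus in single_family + decoy_pool + multis + shorts:
        chrom_items[chrom_cycle % config.n_chromosomes].append([locus])
        chrom_cycle += 1
    for items in chrom_items:
        rng.shuffle(items)

    # --- lay out chromosomes
    genome: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    cds_fa: dict[str, str] = {}
    prot_fa: dict[str, str] = {}
    planted_consensi = {e.name: e.consensus for e in load_dictionary()}
    for name, _ in config.promoter_elements_planted:
        if name not in planted_consensi:
            raise ValueError(f"unknown promoter element {name!r}")

    for ci, items in enumerate(chrom_items):
        chrom_name = f"Chr{ci + 1}"
        chrom = list(_random_dna(rng, config.chromosome_length))
        cursor = 2200 + int(rng.integers(0, 300))
        for block in items:
            for locus in block:
                L = len(locus.seq_local)
                start = cursor  # 1-based genomic start of the region
                end = start + L - 1
                if end > config.chromosome_length - 2100:
                    raise ValueError(
                        f"config infeasible: genes do not fit on {chrom_name} "
                        f"(length {config.chromosome_length})"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                region = locus.seq_local if strand == "+" else reverse_complement(locus.seq_local)
                chrom[start - 1 : end] = list(region)

                def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
                    s, e = iv
                    if strand == "+":
                        return start + s - 1, start + e - 1
                    return start + (L - e), start + (L - s)

                gff_lines.append(
                    f"{chrom_name}\tgenefamkit\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={locus.gene_id}"
                )
                for t in locus.transcripts:
                    gff_lines.append(
                        f"{chrom_name}\tgenefamkit\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                        f"ID={t.transcript_id};Parent={locus.gene_id}"
                    )
                    for iv in t.exons:
                        gs, ge = to_genomic(iv)
                        gff_lines.append(
                            f"{chrom_name}\tgenefamkit\texon\t{gs}\t{ge}\t.\t{strand}\t.\t"
                            f"Parent={t.transcript_id}"
                        )
                    phase = 0
                    cds_local = t.cds if strand == "+" else list(reversed(t.cds))
                    for iv in cds_local:
                        gs, ge = to_genomic(iv)
                        gff_lines.append(
                            f"{chrom_name}\tgenefamkit\tCDS\t{gs}\t{ge}\t.\t{strand}\t{phase}\t"
                            f"Parent={t.transcript_id}"
                        )
                        phase = (3 - ((iv[1] - iv[0] + 1 - phase) % 3)) % 3
                    cds_fa[t.transcript_id] = t.cds_seq
                    prot_fa[t.transcript_id] = translate_cds(t.cds_seq).rstrip("*")

                # plant the promoter of family genes
                if locus.kind == "family" and config.promoter_elements_planted:
                    window, placements = _plant_promoter(
                        rng, config.promoter_length,
                        config.promoter_elements_planted, planted_consensi,
                    )
                    tss_local = locus.cds_start_local
                    if strand == "+":
                        tss = start + tss_local - 1
                        chrom[tss - 1 - config.promoter_length : tss - 1] = list(window)
                    else:
                        tss = start + (L - tss_local)
                        chrom[tss : tss + config.promoter_length] = list(
                            reverse_complement(window)
                        )
                    truth.cis_elements[locus.gene_id] = placements
                cursor = end + 4300 + int(rng.integers(0, 300))
        genome[chrom_name] = "".join(chrom)

    truth.family_gene_ids.sort()
    return SyntheticBundle(
        genome=genome,
        gff3="\n".join(gff_lines) + "\n",
        cds=dict(sorted(cds_fa.items())),
        proteins=dict(sorted(prot_fa.items())),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression and qPCR tables


def generate_expression(
    genes: int | list[str],
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    effects: dict[tuple[str, str], float] | None = None,
    noise: float = 0.0,
    seed: int | None = None,
    base_mean: float = 30.0,
) -> pd.DataFrame:
    """FPKM matrix (genes x tissues) with planted tissue-specific
    fold-change effects and multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    names = [f"gene{i + 1}" for i in range(genes)] if isinstance(genes, int) else list(genes)
    effects = effects or {}
    for (g, t), fold in effects.items():
        if fold < 0:
            raise ValueError(f"negative fold-change for ({g}, {t})")
    base = base_mean * rng.lognormal(0.0, 0.6, size=len(names))
    values = np.empty((len(names), len(tissues)))
    for i, g in enumerate(names):
        for j, t in enumerate(tissues):
            fold = effects.get((g, t), 1.0)
            v = base[i] * fold
            if noise > 0:
                v *= math.exp(rng.normal(0.0, noise))
            values[i, j] = v
    return pd.DataFrame(values, index=names, columns=list(tissues))


def generate_qpcr(
    genes: list[str],
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS,
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS,
    ddct_effects: dict[tuple[str, str, int], float] | None = None,
    sd: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int | None = None,
    reference: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """qPCR Ct table: one row per (gene, treatment, timepoint, biological
    replicate, technical replicate), reference-gene rows included.

    ``ddct_effects[(gene, treatment, timepoint)]`` shifts that cell's
    ΔCt by the given amount relative to the 0 h calibrator, so the
    recovered relative expression is 2^(-effect); with sd = 0 the
    round-trip is exact.
    """
    if not reference:
        raise ValueError("a reference gene is required in the design")
    rng = np.random.default_rng(seed)
    ddct_effects = ddct_effects or {}
    base_dct = {g: float(rng.uniform(4.0, 8.0)) for g in genes}
    ref_base = 20.0
    rows = []
    for trt in treatments:
        for tp in timepoints:
            for bio in range(1, n_bio + 1):
                bio_ref = rng.normal(0.0, sd) if sd > 0 else 0.0
                for tech in range(1, n_tech + 1):
                    tech_ref = rng.normal(0.0, sd) if sd > 0 else 0.0
                    rows.append((reference, trt, tp, bio, tech,
                                 ref_base + bio_ref + tech_ref))
                for g in genes:
                    eff = ddct_effects.get((g, trt, tp), 0.0)
                    bio_g = rng.normal(0.0, sd) if sd > 0 else 0.0
                    for tech in range(1, n_tech + 1):
                        tech_g = rng.normal(0.0, sd) if sd > 0 else 0.0
                        rows.append((g, trt, tp, bio, tech,
                                     ref_base + base_dct[g] + eff + bio_g + tech_g))
    return pd.DataFrame(
        rows, columns=["gene", "treatment", "timepoint", "bio_rep", "tech_rep", "ct"]
    )
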