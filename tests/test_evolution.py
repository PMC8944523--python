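"""Duplicate detection, Ka/Ks counting, selection classes, divergence times."""

import itertools

import pytest
from Bio.Seq import Seq

from genefamkit.evolution import (
    Ng86Counts,
    classify_duplication,
    classify_selection,
    codon_align,
    detect_duplicates,
    divergence_time,
    identity_bin,
    jukes_cantor,
    load_published_pairs,
    ng86_counts,
    ng86_ka_ks,
    synteny_links,
)
from genefamkit.models import DomainHit, FamilyMember


def _member(name, protein, chrom="Chr1", start=1000, gene_id=None, cds="ATGTAA"):
    return FamilyMember(
        gene_id=gene_id or name, name=name, species_prefix=name[:3],
        family_label=name[3:6], chromosome=chrom, strand="+", start=start,
        end=start + 1000, protein=protein, cds=cds,
        domain_hit=DomainHit(1, 1, 1.0, True),
    )


class TestDetectDuplicates:
    def test_identical_paralogs_reported_at_100(self):
        a = _member("GsoGPX1.1", "MKVLAGWCNQF" * 5)
        b = _member("GsoGPX1.2", "MKVLAGWCNQF" * 5, start=9000)
        pairs = detect_duplicates([a, b])
        assert len(pairs) == 1 and pairs[0].identity == 100.0

    def test_exactly_90pct_not_reported(self):
        # 9 of 10 aligned residues identical: identity exactly 90.0%
        a = _member("GsoGPX1.1", "MKVLAGWCNQ")
        b = _member("GsoGPX1.2", "MKVLAGWCNW", start=9000)
        assert detect_duplicates([a, b]) == []

    def test_dissimilar_pair_not_reported(self):
        a = _member("GsoGPX1.1", "MKVLAGWCNQF")
        b = _member("GsoGPX1.2", "MWWDEHYPRST", start=9000)
        assert detect_duplicates([a, b]) == []


class TestClassifyDuplication:
    def _order(self, ids):
        return {"Chr1": ids}

    def test_three_intervening_genes_is_tandem(self):
        a, b = _member("a", "M", gene_id="ga"), _member("b", "M", gene_id="gb")
        order = self._order(["ga", "x1", "x2", "x3", "gb"])
        assert classify_duplication(a, b, order) == "tandem"

    def test_six_intervening_genes_is_segmental(self):
        a, b = _member("a", "M", gene_id="ga"), _member("b", "M", gene_id="gb")
        order = self._order(["ga"] + [f"x{i}" for i in range(6)] + ["gb"])
        assert classify_duplication(a, b, order) == "segmental"

    def test_five_intervening_boundary_is_tandem(self):
        a, b = _member("a", "M", gene_id="ga"), _member("b", "M", gene_id="gb")
        order = self._order(["ga"] + [f"x{i}" for i in range(5)] + ["gb"])
        assert classify_duplication(a, b, order) == "tandem"

    def test_different_chromosomes_is_segmental(self):
        a = _member("a", "M", gene_id="ga", chrom="Chr1")
        b = _member("b", "M", gene_id="gb", chrom="Chr2")
        order = {"Chr1": ["ga"], "Chr2": ["gb"]}
        assert classify_duplication(a, b, order) == "segmental"

    def test_unplaced_member_is_unknown(self):
        a = _member("a", "M", gene_id="ga", chrom="Chr1")
        b = _member("b", "M", gene_id="gb", chrom="scaffold_9")
        assert classify_duplication(a, b, {"Chr1": ["ga"]}) == "unknown"


class TestCodonAlign:
    def test_identical_cds_gap_free(self):
        cds = "ATGAAACCCGGGTAA"
        cols = codon_align(cds, cds)
        assert all("-" not in a and "-" not in b for a, b in cols)

    def test_whole_codon_deletion_one_gap_column(self):
        a = "ATGAAACCCGGGTGGTAA"
        b = "ATGAAAGGGTGGTAA"  # CCC codon deleted
        cols = codon_align(a, b)
        gaps = [(x, y) for x, y in cols if "-" in x or "-" in y]
        assert gaps == [("CCC", "---")]

    def test_frameshifted_input_fails(self):
        with pytest.raises(ValueError):
            codon_align("ATGAAACC", "ATGAAACCC")

    def test_internal_stop_fails(self):
        with pytest.raises(ValueError):
            codon_align("ATGTAAAAATAA", "ATGAAAAAATAA")


def _oracle_codon(c1: str, c2: str) -> tuple[float, float, float, float]:
    """Independent brute-force NG86 oracle for one codon pair: enumerates
    every ordering of the differing positions with Biopython translation."""

    def aa(codon):
        return str(Seq(codon).translate())

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if aa(alt) != "*" and aa(alt) == aa(codon):
                    s += 1.0 / 3.0
        return s

    diff = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0.0, 0.0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if aa(nxt) == "*":
                blocked = True
            if aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b] or [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    s_sites = (syn_sites(c1) + syn_sites(c2)) / 2.0
    return s_sites, 3.0 - s_sites, sd, nd


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        cds = "ATGAAACCCGGGTGGCATTAA"
        ka, ks = ng86_ka_ks(codon_align(cds, cds))
        assert (ka, ks) == (0.0, 0.0)

    def test_single_synonymous_change(self):
        # TTT -> TTC (both Phe) among 12 otherwise identical codons
        base = "ATGAAACCCGGGTGGCATGAGGACATTGCA"
        a = base + "TTT" + "TAA"
        b = base + "TTC" + "TAA"
        ka, ks = ng86_ka_ks(codon_align(a, b))
        assert ka == 0.0 and ks > 0.0
        c = ng86_counts(codon_align(a, b))
        s, n, sd, nd = _oracle_codon("TTT", "TTC")
        assert (c.s_diffs, c.n_diffs) == (sd, nd) == (1.0, 0.0)

    def test_single_nonsynonymous_change(self):
        base = "ATGAAACCCGGGTGGCATGAGGACATTGCA"
        a = base + "AAA" + "TAA"
        b = base + "GAA" + "TAA"
        ka, ks = ng86_ka_ks(codon_align(a, b))
        assert ks == 0.0 and ka > 0.0

    def test_symmetric_in_arguments(self):
        base = "ATGAAACCCGGGTGGCATGAGGACATTGCA"
        a = base + "TTT" + "AAA" + "TAA"
        b = base + "TTC" + "GAA" + "TAA"
        assert ng86_ka_ks(codon_align(a, b)) == pytest.approx(
            ng86_ka_ks(codon_align(b, a))
        )

    def test_correction_at_least_uncorrected_p(self):
        base = "ATGAAACCCGGGTGGCATGAGGACATTGCA"
        a = base + "TTT" + "AAA" + "TAA"
        b = base + "TTC" + "GAA" + "TAA"
        c = ng86_counts(codon_align(a, b))
        ka, ks = ng86_ka_ks(codon_align(a, b))
        assert ks >= c.ps and ka >= c.pn

    def test_jukes_cantor_domain(self):
        with pytest.raises(ValueError):
            jukes_cantor(0.75)

    def test_counts_match_oracle_on_one_diff_pairs(self):
        """Spot sample of single-difference codon pairs against the
        enumeration oracle (the exhaustive sweep lives in the acceptance
        suite)."""
        from genefamkit._codon import SENSE_CODONS, pathway_differences
        from genefamkit._codon import codon_site_counts

        for c1 in SENSE_CODONS[::7]:
            for pos in range(3):
                for nt in "ACGT":
                    if nt == c1[pos]:
                        continue
                    c2 = c1[:pos] + nt + c1[pos + 1:]
                    if c2 not in SENSE_CODONS:
                        continue
                    s, n, sd, nd = _oracle_codon(c1, c2)
                    assert pathway_differences(c1, c2) == pytest.approx((sd, nd))
                    s1 = codon_site_counts(c1)[0]
                    s2 = codon_site_counts(c2)[0]
                    assert (s1 + s2) / 2 == pytest.approx(s)


class TestSelectionClass:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (1.298, "positive"),
            (0.656, "purifying"),
            (0.970, "neutral"),
            (0.941, "purifying"),
            (1.051, "positive"),
            (2.637, "positive"),
        ],
    )
    def test_published_ratios(self, ratio, expected):
        cls, r = classify_selection(ratio, 1.0)
        assert cls == expected and r == pytest.approx(ratio)

    def test_degenerate_zero_ks_with_ka(self):
        cls, r = classify_selection(0.033, 0.0)
        assert cls == "purifying" and r is None

    def test_both_zero_is_identical(self):
        cls, r = classify_selection(0.0, 0.0)
        assert cls == "identical" and r is None

    def test_negative_rate_fails(self):
        with pytest.raises(ValueError):
            classify_selection(-0.1, 0.2)


class TestDivergenceTime:
    @pytest.mark.parametrize(
        "ks,expected", [(0.051, 4.18), (0.0, 0.0), (0.122, 10.0)]
    )
    def test_known_times(self, ks, expected):
        assert round(divergence_time(ks), 2) == expected

    def test_negative_ks_fails(self):
        with pytest.raises(ValueError):
            divergence_time(-0.01)

    def test_full_published_table_reproduced(self):
        """Every published divergence time follows from its Ks via
        T = Ks / (2 x 6.1e-9)."""
        table = load_published_pairs()
        for row in table.itertuples(index=False):
            assert round(divergence_time(row.ks), 2) == pytest.approx(
                row.reported_time_mya
            )


class TestSynteny:
    def test_identity_bins(self):
        assert identity_bin(45.0) == "<=50"
        assert identity_bin(65.0) == "<=70"
        assert identity_bin(85.0) == "<=90"
        assert identity_bin(95.0) == ">90"

    def test_identical_proteins_top_bin(self):
        prot = "MKVLAGWCNQFHED" * 8
        links = synteny_links({"q": prot}, {"s": prot}, seed=0)
        assert len(links) == 1 and links[0].bin == ">90"

    def test_random_proteins_no_significant_links(self):
        import numpy as np

        rng = np.random.default_rng(1)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        qs = {f"q{i}": "".join(aas[rng.integers(0, 20, 120)]) for i in range(3)}
        ss = {f"s{i}": "".join(aas[rng.integers(0, 20, 120)]) for i in range(3)}
        assert synteny_links(qs, ss, seed=0) == []


def test_planted_pairs_fully_recovered(bundle, species, members):
    """Detection and classification reproduce the planted duplicate pairs
    and their tandem/segmental types exactly."""
    from genefamkit.evolution import analyze_duplicates

    pairs = analyze_duplicates(members, species)
    by_gene = {m.name: m.gene_id for m in members}
    got = {frozenset((by_gene[p.member_a], by_gene[p.member_b])): p.duplication_type
           for p in pairs}
    want = {frozenset((t["gene_a"], t["gene_b"])): t["type"]
            for t in bundle.truth.duplicate_pairs}
    assert got == want
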