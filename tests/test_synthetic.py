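"""The synthetic bundle generator: determinism, GFF3 consistency, planted
structure, controlled divergence, expression and qPCR tables."""

import filecmp

import numpy as np
import pytest

from genefamkit._codon import translate_cds
from genefamkit.evolution import ng86_ka_ks
from genefamkit.expression import heatmap_matrix, relative_expression
from genefamkit.io import read_bundle
from genefamkit.synthetic import (
    SyntheticConfig,
    evolve_duplicate,
    generate_bundle,
    generate_expression,
    generate_qpcr,
)


class TestDeterminism:
    def test_bundles_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_family_genes=4, n_decoy_genes=3,
                              tandem_pairs=[(0.05, 0.01)], segmental_pairs=[])
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_bundle(cfg).write(d1)
        generate_bundle(cfg).write(d2)
        for fn in ("genome.fa", "annotation.gff3", "cds.fa", "proteins.fa",
                   "ground_truth.json"):
            assert filecmp.cmp(d1 / fn, d2 / fn, shallow=False), fn


class TestConfigValidation:
    def test_pairs_exceeding_family_size_fail(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_family_genes=2,
                            tandem_pairs=[(0.05, 0.01)],
                            segmental_pairs=[(0.05, 0.01)]).validate()

    def test_negative_targets_fail(self):
        with pytest.raises(ValueError):
            SyntheticConfig(tandem_pairs=[(-0.1, 0.01)]).validate()

    def test_genes_not_fitting_fail(self):
        cfg = SyntheticConfig(seed=0, n_chromosomes=1, chromosome_length=12_000,
                              n_family_genes=8, segmental_pairs=[])
        with pytest.raises(ValueError, match="infeasible|too short"):
            generate_bundle(cfg)


class TestBundleContents:
    def test_gff3_round_trips_through_gffutils(self, bundle, tmp_path):
        paths = bundle.write(tmp_path / "bundle")
        loaded = read_bundle(paths["gff3"], paths["genome"], paths["cds"],
                             paths["proteins"])
        in_memory = bundle.to_species_bundle()
        assert set(loaded.genes) == set(in_memory.genes)
        for gid, gene in loaded.genes.items():
            ref = in_memory.genes[gid]
            assert (gene.chromosome, gene.strand, gene.start, gene.end) == (
                ref.chromosome, ref.strand, ref.start, ref.end)
            assert {t.transcript_id: (t.exons, t.cds) for t in gene.transcripts} == {
                t.transcript_id: (t.exons, t.cds) for t in ref.transcripts}

    def test_cds_matches_genome_coordinates(self, bundle, species):
        """Splicing the genome at the annotated CDS intervals and reverse
        complementing on '-' reproduces each transcript's CDS FASTA entry."""
        from genefamkit._codon import reverse_complement

        for gene in species.genes.values():
            chrom = species.genome[gene.chromosome]
            for t in gene.transcripts:
                spliced = "".join(chrom[s - 1:e] for s, e in sorted(t.cds))
                if gene.strand == "-":
                    spliced = reverse_complement(spliced)
                assert spliced == species.cds[t.transcript_id], t.transcript_id

    def test_strands_mixed(self, species):
        strands = {g.strand for g in species.genes.values()}
        assert strands == {"+", "-"}

    def test_multi_isoform_loci_have_two_lengths(self, species):
        multi = [g for g in species.genes.values() if len(g.transcripts) >= 2]
        assert len(multi) == 2
        for g in multi:
            lengths = {t.cds_length for t in g.transcripts}
            assert len(lengths) >= 2

    def test_short_decoys_under_150bp(self, bundle, species):
        short = [
            g for g in species.genes.values()
            if len(g.transcripts) == 1
            and g.transcripts[0].cds_length < 150
        ]
        assert len(short) == 2
        for g in short:
            assert g.gene_id not in bundle.truth.family_gene_ids

    def test_family_cds_translate_cleanly(self, bundle, species, domain_model):
        """Family CDSs translate without internal stops and carry a complete
        domain signature (evolved duplicates may hold a substitution inside
        the domain, so a complete scan hit is the right criterion)."""
        from genefamkit.identify import scan_domain

        for gid in bundle.truth.family_gene_ids:
            tid = species.genes[gid].transcripts[0].transcript_id
            aa = translate_cds(species.cds[tid])
            assert aa.endswith("*") and "*" not in aa[:-1]
            hit = scan_domain(aa.rstrip("*"), domain_model)
            assert hit is not None and hit.complete


class TestEvolveDuplicate:
    CDS = "ATG" + "AAACCCGGGTGGCATGAGGACATT" * 8 + "TAA"

    def test_zero_targets_identity(self):
        assert evolve_duplicate(self.CDS, 0.0, 0.0, seed=1) == self.CDS

    def test_frame_and_stops_preserved(self):
        out = evolve_duplicate(self.CDS, 0.3, 0.1, seed=2)
        aa = translate_cds(out)
        assert len(out) == len(self.CDS)
        assert aa.endswith("*") and "*" not in aa[:-1]

    def test_jc_domain_failure(self):
        with pytest.raises(ValueError, match="Jukes-Cantor|too large"):
            evolve_duplicate(self.CDS, 1e9, 0.01, seed=1)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            evolve_duplicate("ATGTAAATGTAA", 0.1, 0.1, seed=1)

    def test_mean_recovery_at_moderate_targets(self):
        """Parameter recovery sanity at (Ks, Ka) = (0.05, 0.01) over 60
        seeds (the deeper sweep is in the acceptance suite)."""
        rng = np.random.default_rng(0)
        from genefamkit.synthetic import _random_cds

        cds = _random_cds(rng, 400)
        kas, kss = [], []
        for s in range(60):
            mut = evolve_duplicate(cds, 0.05, 0.01, seed=s)
            aln = [(cds[i:i + 3], mut[i:i + 3]) for i in range(0, len(cds) - 3, 3)]
            ka, ks = ng86_ka_ks(aln)
            kas.append(ka)
            kss.append(ks)
        assert np.mean(kss) == pytest.approx(0.05, rel=0.15)
        assert np.mean(kas) == pytest.approx(0.01, rel=0.15)


class TestExpressionGenerator:
    def test_zero_noise_fold_changes_exact(self):
        m = generate_expression(["g1", "g2"], tissues=("root", "leaf"),
                                effects={("g1", "leaf"): 8.0}, noise=0.0, seed=3)
        assert m.loc["g1", "leaf"] / m.loc["g1", "root"] == pytest.approx(8.0)
        assert m.loc["g2", "leaf"] == pytest.approx(m.loc["g2", "root"])

    def test_fixed_seed_reproducible(self):
        a = generate_expression(5, noise=0.3, seed=11)
        b = generate_expression(5, noise=0.3, seed=11)
        assert a.equals(b)

    def test_negative_fold_fails(self):
        with pytest.raises(ValueError):
            generate_expression(2, effects={("gene1", "root"): -2.0})

    def test_planted_leaf_effect_is_top_centered_value(self):
        m = generate_expression(6, effects={("gene3", "leaf"): 8.0},
                                noise=0.05, seed=7)
        centered = heatmap_matrix(m)
        assert centered.loc["gene3"].idxmax() == "leaf"
        assert centered.stack().idxmax() == ("gene3", "leaf")


class TestQpcrGenerator:
    def test_zero_effect_gives_unit_expression(self):
        t = generate_qpcr(["gA"], sd=0.0, seed=1)
        rel = relative_expression(t, "gA", "GsoActin-11", "NaCl")
        assert rel["mean"].tolist() == pytest.approx([1.0] * 4)

    def test_minus_one_effect_gives_twofold(self):
        t = generate_qpcr(["gA"], ddct_effects={("gA", "PEG", 6): -1.0},
                          sd=0.0, seed=1)
        rel = relative_expression(t, "gA", "GsoActin-11", "PEG")
        assert rel.set_index("timepoint").loc[6, "mean"] == pytest.approx(2.0)

    def test_missing_reference_fails(self):
        with pytest.raises(ValueError):
            generate_qpcr(["gA"], reference="")

    def test_design_complete(self):
        t = generate_qpcr(["gA", "gB"], sd=0.1, seed=2)
        cells = t.groupby(["gene", "treatment", "timepoint", "bio_rep"]).size()
        assert (cells == 3).all()
        assert set(t["gene"]) == {"gA", "gB", "GsoActin-11"}
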