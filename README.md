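# genefamkit

A toolkit for the classic genome-wide gene-family survey, written for
plant comparative genomicists who characterize families like the
superoxide dismutase (SOD) and glutathione peroxidase (GPX) antioxidant
genes of cultivated and wild soybean: identify and name the members,
summarise their proteins, build a phylogeny, scan promoters for
cis-regulatory elements, classify duplications, infer selection and
divergence times, and analyse expression and qPCR responses.

The whole workflow runs on synthetic species bundles with known ground
truth, so every stage is testable end-to-end without genome downloads.

## What it computes

* **Identification** — longest transcript per locus, CDS ≥ 150 bp, no
  truncated proteins, complete domain signature (ungapped PSSM scan);
  members named `GsoGPX2.4`-style (species prefix + family + chromosome
  + ordinal by position).
* **Protein properties** — length, molecular weight (average residue
  masses + water, kDa), isoelectric point (Henderson–Hasselbalch net
  charge, bisected to 1e-4 pH).
* **Phylogenetics** — <50% identity filter, progressive alignment,
  Poisson-corrected distances d = −ln(1−p), Saitou–Nei neighbor
  joining, column-resampling bootstrap supports.
* **Structure & promoters** — exon/intron/UTR summaries; 2000 bp
  upstream of the translation start scanned on both strands against an
  IUPAC dictionary of plant cis-elements (ABRE, MYB, TGACG-motif, ...).
* **Duplication & evolution** — duplicate pairs at >90% protein
  identity; tandem (≤5 intervening genes) vs segmental; Nei–Gojobori
  Ka/Ks with Jukes–Cantor correction; purifying/neutral/positive
  selection around Ka/Ks = 1; divergence time T = Ks/(2λ),
  λ = 6.1×10⁻⁹ per site per year for soybean; identity-binned synteny
  links at E ≤ 10⁻¹⁰.
* **Expression & qPCR** — log2(FPKM+1) mean-centered heatmap matrices;
  2^−ΔΔCt relative expression against a reference gene and 0 h
  calibrator; Duncan's multiple range test letters after one-way ANOVA.
* **Synthetic data** — species bundles (genome FASTA + GFF3 + CDS +
  protein FASTA + ground-truth JSON) with planted family members,
  duplicate pairs evolved at chosen (Ks, Ka), promoter elements,
  expression effects and qPCR Ct tables.

## A worked example

```python
from genefamkit.identify import DEFAULT_DOMAIN_CONSENSUS, DomainModel, identify_family
from genefamkit.evolution import analyze_duplicates
from genefamkit.synthetic import SyntheticConfig, generate_bundle

bundle = generate_bundle(SyntheticConfig(seed=1))   # genome + GFF3 + FASTAs
species = bundle.to_species_bundle()
model = DomainModel.from_consensus(DEFAULT_DOMAIN_CONSENSUS, name="GPX")
members = identify_family(species, model, "Gso", "GPX")
for pair in analyze_duplicates(members, species):
    print(pair.member_a, pair.member_b, pair.duplication_type,
          f"Ka={pair.ka:.3f}", f"Ks={pair.ks:.3f}", pair.selection,
          f"{pair.time_mya} Mya")
```

prints

```
GsoGPX1.2 GsoGPX1.3 tandem Ka=0.009 Ks=0.040 purifying 3.25 Mya
GsoGPX2.1 GsoGPX3.1 segmental Ka=0.007 Ks=0.037 purifying 2.99 Mya
GsoGPX4.1 GsoGPX5.1 segmental Ka=0.009 Ks=0.113 purifying 9.28 Mya
```

Those three pairs are exactly the ones the generator planted (one
tandem, two segmental); the estimated Ka and Ks sit near their targets
(0.01/0.05, 0.01/0.05, 0.02/0.10), all pairs are correctly called
purifying (Ka/Ks ≪ 1), and the dates follow from Ks/(2λ) — e.g.
0.113/(2·6.1×10⁻⁹) ≈ 9.3 Mya.

The `examples/` directory holds one short script per capability
(identification, properties, phylogeny, promoter scanning, Ka/Ks and
dating, expression/qPCR), each printing its numbers with a note on what
they mean.  A thin CLI mirrors the library:

```bash
genefamkit simulate --seed 1 --out bundle/
genefamkit identify --gff bundle/annotation.gff3 --genome bundle/genome.fa \
    --cds bundle/cds.fa --proteins bundle/proteins.fa
genefamkit run --config cfg.yaml        # full multi-species pipeline
```

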