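# Methods

`genefamkit` implements the standard desk workflow for characterizing a
plant gene family (the running example is the SOD/GPX antioxidant
families of cultivated and wild soybean): nominate and name members from
a genome annotation, summarise their proteins, build a distance
phylogeny, scan promoters for cis-regulatory elements, classify
duplicate pairs and date them from synonymous divergence, and analyse
expression and qPCR responses.  A synthetic-bundle generator with full
ground truth lets the entire pipeline be validated without downloading
genomes.  This note records the models, the defaults and why, the
numerical choices, and what the synthetic validation does and does not
show.

## Member identification

A locus is represented by its longest-CDS transcript (ties broken by the
lexicographically smallest transcript id, so reruns are stable).  Three
filters follow, and they commute:

1. coding sequences shorter than 150 bp are removed (boundary
   inclusive: 150 bp survives);
2. truncated proteins are removed — operationalised as a broken reading
   frame, an internal stop, or a missing terminal stop;
3. the protein must carry a *complete* family domain.

The domain scan is an ungapped position-specific scoring matrix slid
along the protein.  A hit is complete when a full-length window fits and
its score reaches the model threshold (default 70% of the maximum
score); proteins shorter than the completeness fraction of the model
length (default 0.8) cannot carry a complete domain and return no hit.
The PSSM stands in for profile-HMM search deliberately: the filtering
criterion is a completeness predicate, not a particular tool's E-value,
and externally produced domain-hit tables can be imported instead
(`identify.read_domain_hits`).  Score thresholds are exposed in the
model object because published pipelines rarely state the exact cutoffs
their HMM/SMART searches used.

Accepted members are named `<3-letter species prefix><family
label><chromosome number>.<ordinal>` — e.g. `GsoGPX2.4` is the 4th GPX
gene on chromosome 2 of *Glycine soja* — with ordinals assigned by
ascending start coordinate per chromosome.  Genes on unplaced scaffolds
receive the pseudo-chromosome token `U`, a convention this package adds
because naming schemes in the literature only cover placed chromosomes.

## Protein properties

Molecular weight is the sum of average residue masses plus one water
(18.01528 Da), reported in kDa; `X` scores the mean residue mass.  The
isoelectric point solves net-charge(pH) = 0 by bisection on [0, 14] to
1e-4 pH units; the charge is a Henderson–Hasselbalch sum over the
termini and D, E, C, Y (acidic) and H, K, R (basic) side chains and is
strictly decreasing in pH, so the root exists and is unique.  The pKa
set is an EMBOSS-style table shipped as JSON and swappable: published
tables (EMBOSS, Bjellqvist/ProtParam, Lehninger) differ by a few tenths
of a pH unit, so the tests assert internal consistency (zero charge at
the returned pH, permutation invariance, monotone response to adding
charged residues) rather than equality with any one web tool.

## Phylogenetics

Pairwise global alignment is Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10, extend 0.5 — all swappable), and percent
identity counts identical columns over all alignment columns, gaps
included in the denominator.  Before tree building, sequences whose
*best* identity to any other input is below 50% are removed; the
max-to-any-other reading keeps the filter symmetric and total where a
reference sequence is not named, and a singleton input passes trivially.

The bundled multiple aligner is progressive: a UPGMA guide tree on
identity distances, then profile–profile dynamic programming with
column scores averaged over residue pairs (linear gap cost per profile
column, deterministic diagonal-first traceback).  It is intentionally
simple — adequate for families that passed a 50% identity filter — and
externally computed alignments can be supplied wherever an `Msa` is
accepted.

Distances are Poisson-corrected amino-acid distances d = −ln(1 − p)
with p the mismatch fraction over columns where neither row is gapped
(pairwise deletion; gap treatment is a choice this package fixes because
published trees rarely state it).  p ≥ 1 or zero comparable columns is
reported as a saturation failure for that pair; only the bootstrap's
resampled replicates cap p just below 1 instead, so a replicate never
aborts the run.

Neighbor joining follows Saitou & Nei: join the pair minimising
Q(i,j) = (n−2)d(i,j) − r_i − r_j, ties broken by the lexicographically
smallest name pair.  Negative branch lengths are clamped to zero with
the deficit moved to the sibling edge so the joined pair's total is
preserved — standard practice where the literature is silent.  The last
three lineages are resolved by the closed-form star formulas, so the
returned root is the unrooted tree's trifurcation.  On additive
distances the implementation reproduces the generating tree's path
lengths exactly (property-tested against random trees, n ≤ 8) and its
topologies agree with scikit-bio's independent NJ.  Bootstrap support is
the percentage of column-resampled replicates containing each original
bipartition, driven by a single seeded generator (default 1000
replicates in the pipeline).

## Gene structure and promoters

Introns are the gaps between consecutive exons; UTR segments are exon
minus CDS intervals.  Coordinates are GFF3 1-based inclusive externally
and converted to gene-local 5'→3' coordinates for reporting, so plus-
and minus-strand structures are directly comparable.

Promoters are the 2000 bp upstream of the *translation start site*
(first CDS base): on the plus strand the window [start−2000, start−1]
in genome coordinates; on the minus strand the reverse complement of
[start+1, start+2000].  Windows truncated by a chromosome end are
returned shorter with a warning.  The cis-element dictionary is an
editable TSV of IUPAC consensus strings seeded with commonly scanned
plant elements (ABRE, MYB, MYC, MBS, ARE, LTR, TGACG-/CGTCA-motif,
G-box, W-box, circadian, ...).  The consensus strings follow published
database entries but the database itself is not redistributed, so exact
hit parity with any web scanner is not claimed.  Scanning reports every
match on both strands (flag-controlled; whether published scans covered
both strands is usually unstated), overlaps included; reverse-strand
hits are reported at the leftmost window coordinate they cover, and
reverse-complement element pairs are kept as distinct names, mirroring
database output.  A per-gene × element count matrix with an optional
minimum-total column filter (the "more than 15 occurrences" selection
used in overview figures) completes the stage.

## Duplication and molecular evolution

Candidate duplicates are unordered member pairs with global protein
identity strictly above 90%.  A pair is *tandem* when both genes share
a chromosome with at most 5 annotated genes between them, otherwise
*segmental* (including all cross-chromosome pairs); unplaced members
classify as unknown.

Ka/Ks uses Nei–Gojobori (1986) counting on a protein-guided codon
alignment (gapped codon columns excluded).  Potential synonymous sites
are each position's synonymous fraction among its three alternative
nucleotides, averaged over the two sequences; changes *to* stop codons
count as nonsynonymous sites, the common convention.  Observed
differences are averaged over all minimal mutational pathways with equal
weights, excluding pathways through stops (if every pathway is blocked,
all are used — only possible for 2–3-difference codons and rare).
Proportions are Jukes–Cantor corrected, d = −(3/4)ln(1 − 4p/3),
undefined at p ≥ 3/4 and reported as an explicit failure for that rate.
The counting is verified exhaustively against an independent
enumeration oracle over every sense-codon pair with ≤ 2 differences.

Selection classes use a neutral band of [0.95, 1.05] around Ka/Ks = 1 —
the narrowest symmetric band consistent with the published soybean
SOD/GPX labels this package re-derives (0.941 → purifying, 0.970 →
neutral, 1.051 → positive) — exposed in configuration.  Ks = 0 with
Ka > 0 leaves the ratio undefined; the pair is labelled purifying and
flagged degenerate, matching how such rows are reported in practice.
Divergence time is T = Ks/(2λ) with λ = 6.1e-9 synonymous substitutions
per site per year (the soybean rate; per-clade override available),
reported in Mya to two decimals.

Synteny links are all-vs-all global alignments kept at E ≤ 1e-10 and
binned by identity (≤50 / ≤70 / ≤90 / >90%).  The E-value comes from an
extreme-value (Gumbel) model fitted at startup to scores of shuffled
sequence pairs — a score null in the Karlin–Altschul spirit, fitted
empirically because the pipeline aligns globally rather than running a
local-alignment search tool.  Identical proteins score far into the
tail (E ≈ 1e-30); unrelated random proteins are never significant at
the threshold.

## Expression and qPCR

The heatmap transform is log2(FPKM + 1) followed by per-gene mean
centering; rows therefore have exactly zero mean, and the transform is
monotone per entry before centering.  The tissue report ranks tissues
per gene on the transformed scale and flags genes whose top tissue
exceeds the runner-up by a margin (default 1.0 log2 unit = two-fold).

Relative expression follows the standard 2^−ΔΔCt convention: technical
replicates collapse to one Ct by their mean (the 3×3 design does not
state the collapse; the mean is the standard choice), ΔCt = target −
reference per biological replicate, ΔΔCt subtracts the mean calibrator
ΔCt (same treatment at 0 h), and the result is summarised as mean ± sd
over biological replicates.  A missing reference measurement fails
naming the design cell.

Duncan's multiple range test runs on the one-way ANOVA mean square
error: means sorted descending, a span of p ordered means significant
when its range reaches R_p = q(α_p, p, df)·√(MSE/n) with protection
level α_p = 1 − (1−α)^(p−1); the studentized-range quantiles are
computed numerically (scipy) rather than read from printed tables, so
any df is supported, and they are cached because the quantile function
is expensive.  Letters come from the standard sweep over maximal
non-significant runs, 'a' on the largest mean.  Unbalanced designs use
the harmonic mean group size with a warning; zero within-group variance
with unequal means makes every real difference significant.

**Design choice — F-protection.**  The unprotected range test's
family-wise error under a complete null equals its top protection level
(1 − 0.95^3 ≈ 0.14 for four groups), not α.  Because the test is
specified and used here as a post-ANOVA procedure, `duncan_mrt` defaults
to requiring a significant one-way F-test at α first (all groups share
one letter otherwise), which keeps the all-null false-labeling rate at
the nominal ~5%; the unprotected variant remains available via
`f_protect=False`.

## The synthetic-data generator

`generate_bundle` emits a species bundle (genome FASTA, GFF3, CDS and
protein FASTA, JSON ground truth) whose statistical structure matches
what the analysis assumes, under a single seeded generator — a fixed
seed gives byte-identical files.

* **Family genes** share a 180-residue template carrying a 40-residue
  domain signature; each member substitutes non-domain residues at rate
  0.18.  That places non-pair members at ~76% mean pairwise identity:
  comfortably above the 50% homology filter and ~5 standard deviations
  below the >90% duplicate threshold, so only planted pairs are ever
  detected.  Proteins are back-translated with uniformly random
  synonymous codons and a terminal stop.
* **Duplicate pairs** (default one tandem pair at Ks 0.05/Ka 0.01 and
  two segmental pairs at 0.05/0.01 and 0.10/0.02, echoing the magnitude
  of published soybean estimates) are created by `evolve_duplicate`.
  The target rates are inverted through Jukes–Cantor to proportions;
  each codon then receives at most one substitution — synonymous with
  probability pS × (its synonymous sites), nonsynonymous with
  pN × (its nonsynonymous sites), position chosen proportionally to the
  per-position fraction, stops never introduced.  One hit per codon
  keeps the NG86 difference counting free of pathway ambiguity, so the
  expected estimates equal the targets exactly (a naive per-site scheme
  lets codons take two hits, whose pathway averaging inflates Ks by
  ~10% when Ka ≫ Ks); multiple hits are represented through the JC
  transform rather than simulated.  Measured recovery is within ~3% of
  target at all tested points.  Targets too large for one hit per codon
  (λ_s + λ_n > 1) or outside the JC domain fail explicitly.
* **Decoys**: random-protein loci, multi-isoform loci whose two
  isoforms share codon-aligned exons but differ in CDS length, and
  sub-150 bp CDS decoys — exercising the longest-transcript, length and
  domain filters.
* **Genome layout**: i.i.d. uniform intergenic sequence; genes on mixed
  strands with 6–8 exons (family), UTRs in the terminal exons, and
  enough spacing that every gene keeps a 2000 bp promoter flank.
  Tandem-pair members are placed with ≤ 2 intervening decoys; segmental
  members on different chromosomes.  An infeasible layout (genes do not
  fit) fails explicitly.
* **Promoters** of family genes are overwritten with random sequence
  carrying exactly the configured element copies (default 3× ABRE,
  2× TGACG-motif).  Placements keep a margin between planted spans and
  accidental matches of the planted element names — either strand — are
  scrubbed by redrawing unprotected bases, so downstream scans count
  exactly the planted copies for those elements.  Counts for
  *unplanted* elements remain chance matches and are not controlled.
* **Expression / qPCR**: FPKM matrices with multiplicative log-normal
  noise and planted fold-changes (exact at zero noise); Ct tables over
  the stress design (H2O2 / NaCl / PEG × 0/3/6/12 h × 3 biological × 3
  technical replicates, actin reference) with planted ΔΔCt effects and
  Gaussian replicate noise — at sd = 0 the 2^−ΔΔCt round trip is exact.

What passing on synthetic bundles shows — and does not.  The generator
proves the machinery: filters act at their boundaries, planted members
and pairs are recovered with recall = precision = 1, planted divergences
and effects are re-estimated without bias.  It does not emulate real
genome composition (repeats, GC structure, pseudogenes), alternative
splicing beyond simple exon skipping, codon-usage bias, or alignment
ambiguity in diverged families; results on real genomes additionally
depend on assembly and annotation quality, which no synthetic test can
certify.

## Problem sizes and determinism

Default study conditions: 6 chromosomes × 120 kb, 8 family genes (3 of
them in planted pairs), 12 decoy loci.  Validation sweeps use 200
seeds × 500-codon sequences for parameter recovery and 2000 simulations
for the Duncan null rate — sizes at which Monte-Carlo error is a few
percent of the quantities checked.  Every stochastic step (bundle
generation, bootstrap, simulations) flows from one seed, and the
pipeline's outputs are byte-identical across reruns with a fixed
configuration.

## Known limitations

* The progressive aligner has no iterative refinement; for distant
  families import a dedicated aligner's output.
* NG86 with equal pathway weights underestimates Ka/Ks heterogeneity
  relative to ML codon models; it is the counting method of record for
  this workflow, not the state of the art.
* The synteny E-value model calibrates on shuffled sequences at
  startup; it ranks links sensibly but is not comparable across runs
  with different input sets.
* Subcellular localization is a pass-through annotation, never
  predicted.
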