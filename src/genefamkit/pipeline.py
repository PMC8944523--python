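"""End-to-end pipeline: identify -> properties -> phylogeny -> structure &
promoters -> duplication/evolution -> expression, per species bundle, with
per-stage TSV outputs and a machine-readable JSON report.

Every stage is a pure function of its inputs, the configuration and the
seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import evolution, expression, phylo, promoter, properties, structure
from .identify import DEFAULT_DOMAIN_CONSENSUS, DomainModel, identify_family, select_longest_transcript
from .io import read_bundle, write_tsv
from .models import FamilyMember

log = logging.getLogger("genefamkit")


@dataclass
class BundleSpec:
    prefix: str  # 3-letter species prefix, e.g. Gso
    gff3: str
    genome: str
    cds: str
    proteins: str | None = None
    expression: str | None = None  # FPKM TSV, genes x tissues
    qpcr: str | None = None  # Ct TSV
    qpcr_reference: str = "GsoActin-11"


@dataclass
class PipelineConfig:
    bundles: list[BundleSpec]
    family_label: str = "GPX"
    domain_consensus: str = DEFAULT_DOMAIN_CONSENSUS
    out_dir: str = "genefamkit_out"
    seed: int = 0
    min_cds_bp: int = 150
    identity_filter: float = 50.0
    duplication_identity: float = 90.0
    tandem_max_gap: int = 5
    lam: float = evolution.SOYBEAN_LAMBDA
    bootstrap: int = 1000
    promoter_length: int = 2000
    alpha: float = 0.05
    neutral_band: tuple[float, float] = (0.95, 1.05)
    cis_dictionary: str | None = None

    def validate(self) -> None:
        if not self.bundles:
            raise ValueError("no species bundles configured")
        prefixes = [b.prefix for b in self.bundles]
        if len(prefixes) != len(set(prefixes)):
            raise ValueError("species prefixes must be unique")
        for value, name in [
            (self.min_cds_bp, "min_cds_bp"), (self.identity_filter, "identity_filter"),
            (self.duplication_identity, "duplication_identity"),
            (self.tandem_max_gap, "tandem_max_gap"), (self.lam, "lambda"),
            (self.promoter_length, "promoter_length"), (self.alpha, "alpha"),
        ]:
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not self.domain_consensus:
            raise ValueError("a domain model (consensus) is required")
        for b in self.bundles:
            for path in (b.gff3, b.genome, b.cds):
                if not os.path.exists(path):
                    raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        bundles = [BundleSpec(**b) for b in raw.pop("bundles")]
        if "neutral_band" in raw:
            raw["neutral_band"] = tuple(raw["neutral_band"])
        return cls(bundles=bundles, **raw)


def _members_rows(members: list[FamilyMember]) -> list[dict]:
    return [
        dict(gene_id=m.gene_id, name=m.name, chromosome=m.chromosome,
             start=m.start, end=m.end, strand=m.strand,
             domain_score=round(m.domain_hit.score, 3))
        for m in members
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    model = DomainModel.from_consensus(config.domain_consensus, name=config.family_label)
    dictionary = promoter.load_dictionary(config.cis_dictionary)
    report: dict = {"seed": config.seed, "species": {}}
    all_members: dict[str, list[FamilyMember]] = {}

    for spec in config.bundles:
        out = os.path.join(config.out_dir, spec.prefix)
        os.makedirs(out, exist_ok=True)
        stage = f"[{spec.prefix}]"
        try:
            bundle = read_bundle(spec.gff3, spec.genome, spec.cds, spec.proteins)
        except Exception as exc:  # pragma: no cover - startup validation
            raise RuntimeError(f"{stage} load: {exc}") from exc
        log.info("%s loaded %d gene models", stage, len(bundle.genes))

        members = identify_family(
            bundle, model, spec.prefix, config.family_label, config.min_cds_bp
        )
        log.info("%s identify: %d/%d genes accepted", stage, len(members),
                 len(bundle.genes))
        write_tsv(_members_rows(members), os.path.join(out, "members.tsv"),
                  ["gene_id", "name", "chromosome", "start", "end", "strand",
                   "domain_score"])
        all_members[spec.prefix] = members

        prop_rows = []
        for m in members:
            p = properties.protein_properties(m.protein, m.localization)
            prop_rows.append(dict(name=m.name, length=p.length,
                                  mw_kda=round(p.mw_kda, 3), pi=round(p.pi, 2),
                                  localization=p.localization or ""))
        write_tsv(prop_rows, os.path.join(out, "props.tsv"),
                  ["name", "length", "mw_kda", "pi", "localization"])

        seqs = {m.name: m.protein for m in members}
        retained = phylo.filter_by_identity(seqs, config.identity_filter)
        log.info("%s identity filter: %d/%d retained", stage, len(retained), len(seqs))
        tree_newick = None
        if len(retained) >= 4:
            msa = phylo.progressive_align(retained)
            tree, _ = phylo.bootstrap_support(msa, config.bootstrap, config.seed)
            tree_newick = phylo.to_newick(tree)
            with open(os.path.join(out, "tree.nwk"), "w") as fh:
                fh.write(tree_newick + "\n")

        struct_rows, hit_objs = [], []
        for m in members:
            gene = bundle.genes[m.gene_id]
            tid = select_longest_transcript(gene)
            gs = structure.structure_summary(gene, tid)
            struct_rows.append(dict(name=m.name, exons=gs.exon_count,
                                    introns=gs.intron_count))
            window = promoter.extract_promoter(bundle.genome, gene,
                                               config.promoter_length, tid)
            hit_objs += promoter.scan_cis_elements(window, dictionary, member=m.name)
        write_tsv(struct_rows, os.path.join(out, "structures.tsv"),
                  ["name", "exons", "introns"])
        write_tsv(
            [dict(member=h.member, element=h.element, position=h.position,
                  strand=h.strand, matched=h.matched) for h in hit_objs],
            os.path.join(out, "promoter_hits.tsv"),
            ["member", "element", "position", "strand", "matched"],
        )
        matrix = promoter.element_count_matrix(hit_objs, [m.name for m in members])
        matrix.to_csv(os.path.join(out, "cis_matrix.tsv"), sep="\t")

        pairs = evolution.analyze_duplicates(
            members, bundle, config.duplication_identity, config.lam,
            config.neutral_band,
        )
        log.info("%s duplicates: %d pairs", stage, len(pairs))
        write_tsv(
            [dict(member_a=p.member_a, member_b=p.member_b, identity=p.identity,
                  type=p.duplication_type, ka=round(p.ka, 4), ks=round(p.ks, 4),
                  ka_ks="" if p.ka_ks is None else round(p.ka_ks, 4),
                  selection=p.selection, time_mya=p.time_mya) for p in pairs],
            os.path.join(out, "pairs.tsv"),
            ["member_a", "member_b", "identity", "type", "ka", "ks", "ka_ks",
             "selection", "time_mya"],
        )

        per_chrom: dict[str, int] = {}
        for m in members:
            per_chrom[m.chromosome] = per_chrom.get(m.chromosome, 0) + 1
        report["species"][spec.prefix] = {
            "n_genes_annotated": len(bundle.genes),
            "n_family_members": len(members),
            "members": [m.name for m in members],
            "per_chromosome": dict(sorted(per_chrom.items())),
            "duplicate_pairs": [
                dict(a=p.member_a, b=p.member_b, identity=p.identity,
                     type=p.duplication_type, ka=round(p.ka, 4),
                     ks=round(p.ks, 4),
                     ka_ks=None if p.ka_ks is None else round(p.ka_ks, 4),
                     selection=p.selection, time_mya=p.time_mya)
                for p in pairs
            ],
            "tree": tree_newick,
        }

        if spec.expression:
            import pandas as pd

            fpkm = pd.read_csv(spec.expression, sep="\t", index_col=0)
            expression.heatmap_matrix(fpkm).to_csv(
                os.path.join(out, "expression_heatmap.tsv"), sep="\t"
            )
            expression.tissue_profile_report(fpkm).to_csv(
                os.path.join(out, "tissue_profiles.tsv"), sep="\t", index=False
            )
        if spec.qpcr:
            import pandas as pd

            table = pd.read_csv(spec.qpcr, sep="\t")
            rows = []
            genes = [g for g in table["gene"].unique() if g != spec.qpcr_reference]
            for gene in genes:
                for trt in sorted(table["treatment"].unique()):
                    rel = expression.relative_expression(
                        table, gene, spec.qpcr_reference, trt
                    )
                    for r in rel.itertuples(index=False):
                        rows.append(dict(gene=gene, treatment=trt,
                                         timepoint=r.timepoint,
                                         mean=round(r.mean, 4), sd=round(r.sd, 4)))
            write_tsv(rows, os.path.join(out, "qpcr_results.tsv"),
                      ["gene", "treatment", "timepoint", "mean", "sd"])

    # cross-species: orthologue pairs at 100% identity and synteny links
    prefixes = list(all_members)
    orthologues = []
    links_rows = []
    for i in range(len(prefixes)):
        for j in range(i + 1, len(prefixes)):
            a_members = {m.name: m.protein for m in all_members[prefixes[i]]}
            b_members = {m.name: m.protein for m in all_members[prefixes[j]]}
            if a_members and b_members:
                for link in evolution.synteny_links(a_members, b_members,
                                                    seed=config.seed):
                    links_rows.append(dict(query=link.query, subject=link.subject,
                                           identity=link.identity, bin=link.bin,
                                           e_value=f"{link.e_value:.3e}"))
                    if link.identity == 100.0:
                        orthologues.append([link.query, link.subject])
    write_tsv(links_rows, os.path.join(config.out_dir, "synteny_links.tsv"),
              ["query", "subject", "identity", "bin", "e_value"])
    report["orthologue_pairs_100pct"] = sorted(orthologues)

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
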