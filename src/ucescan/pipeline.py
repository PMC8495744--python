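"""End-to-end orchestration: discover → annotate → controls → motifs →
popgen → enrich → synteny → target report.

Every stage writes machine-readable TSV/JSON into the output directory;
reruns with the same config and seed are byte-identical.  Optional inputs
(VCF, PFMs, orthologs, phenotype table) switch their stages off with a
warning instead of failing.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import annotation, controls, discovery, goenrich, motifs, popgen, synteny
from .mafio import read_maf
from .stats import control_ttest

__all__ = ["PipelineConfig", "run_all", "target_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    maf: str
    reference: str
    gff: str
    outdir: str
    reference_species: str = "ref"
    vcf: str | None = None
    pfms: str | None = None
    orthologs_a: str | None = None
    orthologs_b: str | None = None
    gff_b: str | None = None
    species_b: str | None = None
    go_table: str | None = None
    phenotype_table: str | None = None
    min_run_length: int = 18
    required_species: list[str] | None = None
    n_control_sets: int = 10
    q_threshold: float = 0.05
    fdr_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for name in ("maf", "reference", "gff"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{name} input missing: {p}")
        for thr in (self.q_threshold, self.fdr_threshold):
            if not 0 < thr <= 1:
                raise ValueError(f"threshold {thr} outside (0, 1]")


def run_all(config: PipelineConfig) -> str:
    """Run every stage; returns the output directory."""
    config.validate()
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name: str, **info) -> None:
        logger.info("stage %s done: %s", name, info)
        manifest["stages"].append({"name": name, **info})

    blocks = list(read_maf(config.maf))
    species = sorted({sp for b in blocks for sp in b.species()})
    required = config.required_species or species

    # --- discover ---------------------------------------------------------
    disc_cfg = discovery.DiscoveryConfig(
        reference_species=config.reference_species,
        min_run_length=config.min_run_length,
        required_species=list(required),
    )
    uces = discovery.find_invariant_runs(blocks, disc_cfg)
    fasta = Fasta(config.reference)
    discovery.flag_repeats(uces, fasta)
    discovery.write_bed(uces, os.path.join(out, "uces.bed"))
    stage("discover", n_uces=len(uces),
          invariant_bases=discovery.total_invariant_bases(uces),
          per_chromosome=discovery.per_chromosome_counts(uces))

    # --- annotate ---------------------------------------------------------
    index = annotation.build_feature_index(config.gff)
    profiles = annotation.annotate_records(uces, index)
    discovery.write_uce_table(uces, os.path.join(out, "uces.tsv"))
    at = annotation.at_content(uces) if uces else None
    period = annotation.length_periodicity(uces) if uces else None
    stage("annotate", at_content=at, periodicity=period)

    # --- controls ---------------------------------------------------------
    mask = controls.build_coverage_mask(blocks, required, config.reference_species)
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    maf_sets = controls.sample_controls(
        uces, mode="maf_matched", n_sets=config.n_control_sets,
        seed=config.seed, mask=mask,
    )
    genome_sets = controls.sample_controls(
        uces, mode="genome_matched", n_sets=config.n_control_sets,
        seed=config.seed + 1, chrom_lengths=chrom_lengths, feature_index=index,
    )
    ctrl_dir = os.path.join(out, "controls")
    os.makedirs(ctrl_dir, exist_ok=True)
    for cs in maf_sets + genome_sets:
        controls.write_control_bed(
            cs, os.path.join(ctrl_dir, f"{cs.match_mode}_{cs.set_index}.bed")
        )
    composition = annotation.composition_summary(
        uces, [cs.intervals for cs in maf_sets], index
    )
    with open(os.path.join(out, "composition.json"), "w") as fh:
        json.dump(composition, fh, indent=2)
    stage("controls", mask_bases=controls.mask_total(mask),
          n_sets=config.n_control_sets)

    # --- motifs -----------------------------------------------------------
    cas9_flags, cas9_summary = motifs.cas9_targets(uces)
    motif_summary = None
    if config.pfms:
        pfms = motifs.read_jaspar(config.pfms)
        seqs = {r.id: r.sequence for r in uces}
        hits, has_hit, n_tests = motifs.scan(seqs, pfms, config.q_threshold)
        labels = {r.id: (r.location_class or "unknown", r.chromosome) for r in uces}
        motif_summary = motifs.hit_fraction_summary(has_hit, labels)
        control_fracs = []
        for cs in maf_sets:
            cseqs = {
                f"c{i}": str(fasta[c][s:e]).upper()
                for i, (c, s, e) in enumerate(cs.intervals)
            }
            _, chit, _ = motifs.scan(cseqs, pfms, config.q_threshold)
            control_fracs.append(sum(chit.values()) / max(len(chit), 1))
        cmean, csd, pval = control_ttest(
            motif_summary["fraction_with_hit"], control_fracs
        )
        motif_summary["control_mean"] = cmean
        motif_summary["control_sd"] = csd
        motif_summary["p_value"] = pval
        hits.to_csv(os.path.join(out, "motif_hits.tsv"), sep="\t", index=False)
    else:
        logger.warning("no PFM file: motif scan skipped")
    with open(os.path.join(out, "motif_summary.json"), "w") as fh:
        json.dump({"cas9": cas9_summary, "tfbs": motif_summary}, fh, indent=2)
    stage("motifs", cas9=cas9_summary)

    # --- popgen -----------------------------------------------------------
    region_stats: list[popgen.RegionDiversity] = []
    diversity = None
    if config.vcf and os.path.exists(config.vcf):
        table = popgen.load_variant_table(config.vcf)
        region_stats = popgen.regions_diversity(table, [r.interval for r in uces])
        ctrl_stats = [
            popgen.regions_diversity(table, cs.intervals) for cs in genome_sets
        ]
        labels = {
            r.interval: (r.location_class or "unknown", r.chromosome) for r in uces
        }
        for cs in genome_sets:
            for iv in cs.intervals:
                genic = bool(index.genes_overlapping(*iv))
                labels[iv] = ("genic" if genic else "intergenic", iv[0])
        diversity = popgen.diversity_comparison(region_stats, ctrl_stats, labels)
        rows = [
            {"id": r.id, "S": rd.S, "pi": rd.pi, "D": rd.D, "snp_free": rd.snp_free}
            for r, rd in zip(uces, region_stats)
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(out, "diversity.tsv"), sep="\t", index=False
        )
        with open(os.path.join(out, "diversity_summary.json"), "w") as fh:
            json.dump(diversity, fh, indent=2)
        stage("popgen", n_snp_free=diversity["n_snp_free"])
    else:
        logger.warning("no VCF: popgen stage skipped")

    # --- enrichment -------------------------------------------------------
    gene_spans = index.gene_spans()
    hit_genes = {
        g[2]
        for r in uces
        for g in index.genes_overlapping(r.chromosome, r.start, r.end)
    }
    if config.go_table and os.path.exists(config.go_table):
        go_df = pd.read_csv(config.go_table, sep="\t")
        go_rows = list(go_df.itertuples(index=False, name=None))
        namespaces = {row[1]: row[2] for row in go_rows if len(row) > 2}
        try:
            gtable = goenrich.build_gene_table(gene_spans, hit_genes, go_rows)
            results = goenrich.enrich(gtable, alpha=config.fdr_threshold)
            goenrich.write_results(
                results, os.path.join(out, "enrichment.tsv"), namespaces
            )
            intergenic = [r for r in uces if r.location_class == "intergenic"]
            flank_results = goenrich.flanking_gene_enrichment(
                intergenic, index, gene_spans, go_rows, alpha=config.fdr_threshold
            )
            goenrich.write_results(
                flank_results, os.path.join(out, "enrichment_flanking.tsv"), namespaces
            )
            stage("enrich", n_terms=len(results),
                  n_significant=len(goenrich.significant(results, config.fdr_threshold)))
        except ValueError as exc:
            logger.warning("enrichment skipped: %s", exc)
    else:
        logger.warning("no GO table: enrichment skipped")

    # --- synteny ----------------------------------------------------------
    if all((config.gff_b, config.orthologs_a, config.orthologs_b, config.species_b)):
        index_b = annotation.build_feature_index(config.gff_b)
        ortho_a = synteny.read_ortholog_table(config.orthologs_a)
        ortho_b = synteny.read_ortholog_table(config.orthologs_b)
        lifter = synteny.MafLifter(blocks, config.reference_species)
        genic = synteny.genic_orthology(
            uces, index, index_b, ortho_a, ortho_b, lifter, config.species_b
        )
        intergenic = [r for r in uces if r.location_class == "intergenic"]
        calls, flank_summary = synteny.flank_synteny(
            intergenic, index, index_b, ortho_a, ortho_b, lifter,
            config.species_b, config.reference_species,
        )
        with open(os.path.join(out, "synteny.json"), "w") as fh:
            json.dump({"genic": genic, "flanking": flank_summary}, fh, indent=2)
        stage("synteny", genic=genic)
    else:
        logger.warning("orthology inputs incomplete: synteny skipped")

    # --- target report ----------------------------------------------------
    report = target_report(uces, region_stats, cas9_flags, index,
                           config.phenotype_table)
    report.to_csv(os.path.join(out, "target_report.tsv"), sep="\t", index=False)
    stage("report", n_genes=len(report))

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def target_report(
    uces: Sequence[discovery.UCERecord],
    region_stats: Sequence[popgen.RegionDiversity],
    cas9_flags: dict[str, bool],
    index: annotation.FeatureIndex,
    phenotype_table: str | None = None,
) -> pd.DataFrame:
    """Per-gene gene-drive target suitability ranking.

    Sorted by (SNP-free Cas9-compatible UCE count, total invariant bases)
    descending; when no diversity data exists the first key is zero for
    every gene and the ranking falls back to invariant bases.
    """
    snp_free = {}
    if region_stats:
        by_interval = {(rd.chromosome, rd.start, rd.end): rd for rd in region_stats}
        for r in uces:
            rd = by_interval.get(r.interval)
            snp_free[r.id] = bool(rd and rd.snp_free)

    rows: dict[str, dict] = {}
    for r in uces:
        for g in index.genes_overlapping(r.chromosome, r.start, r.end):
            gid = g[2]
            row = rows.setdefault(gid, {
                "gene_id": gid, "uce_count": 0, "invariant_bases": 0,
                "longest_uce": 0, "snp_free_uces": 0, "cas9_uces": 0,
                "snp_free_cas9_uces": 0, "all_non_repeat": True,
            })
            row["uce_count"] += 1
            row["invariant_bases"] += r.length
            row["longest_uce"] = max(row["longest_uce"], r.length)
            sf = snp_free.get(r.id, False)
            c9 = cas9_flags.get(r.id, False)
            row["snp_free_uces"] += int(sf)
            row["cas9_uces"] += int(c9)
            row["snp_free_cas9_uces"] += int(sf and c9)
            if r.is_repeat:
                row["all_non_repeat"] = False

    df = pd.DataFrame(list(rows.values()) or None, columns=[
        "gene_id", "uce_count", "invariant_bases", "longest_uce",
        "snp_free_uces", "cas9_uces", "snp_free_cas9_uces", "all_non_repeat",
    ])
    for col in ("female_sterile", "lethal_recessive", "p_sterile"):
        df[col] = pd.NA
    if phenotype_table and os.path.exists(phenotype_table):
        pheno = pd.read_csv(phenotype_table, sep="\t").set_index("gene_id")
        for col in ("female_sterile", "lethal_recessive", "p_sterile"):
            if col in pheno.columns:
                df[col] = df["gene_id"].map(pheno[col])
    df = df.sort_values(
        ["snp_free_cas9_uces", "invariant_bases", "gene_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return df
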