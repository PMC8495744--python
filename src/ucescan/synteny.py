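"""Positional conservation of UCEs between species via gene orthology.

Coordinates in the comparator species come from the UCE's own MAF row
(the alignment is the lift); a UCE whose block lacks a comparator row is
missing data.  Genic UCEs are checked through the orthology of their
containing genes; intergenic UCEs through the orthology of their nearest
flanking genes on each side (strand-agnostic), yielding the six-way
category split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import FeatureIndex
from .discovery import UCERecord
from .goenrich import flanking_genes
from .mafio import AlignmentBlock

__all__ = [
    "CATEGORIES",
    "SyntenyCall",
    "MafLifter",
    "genic_orthology",
    "flank_synteny",
    "read_ortholog_table",
]

logger = logging.getLogger(__name__)

CATEGORIES = [
    "both_flanks_match",
    "one_match_one_nomatch",
    "one_match_one_missing",
    "one_nomatch_one_missing",
    "both_missing",
    "both_nomatch",
]


@dataclass
class SyntenyCall:
    uce_id: str
    category: str
    species_pair: tuple[str, str]


def read_ortholog_table(path: str) -> dict[str, str]:
    """TSV with gene_id and orthogroup_id columns (header required)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gi, oi = header.index("gene_id"), header.index("orthogroup_id")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[oi]:
                out[f[gi]] = f[oi]
    return out


class MafLifter:
    """Lift reference intervals into another species via MAF rows."""

    def __init__(self, blocks: Iterable[AlignmentBlock], reference_species: str):
        self.reference_species = reference_species
        self._by_chrom: dict[str, list[tuple[int, int, AlignmentBlock]]] = {}
        for block in blocks:
            ref = block.row_for(reference_species)
            if ref is None:
                continue
            self._by_chrom.setdefault(ref.chromosome, []).append(
                (ref.plus_start(), ref.plus_end(), block)
            )
        for lst in self._by_chrom.values():
            lst.sort()

    def lift(self, chrom: str, start: int, end: int, species: str
             ) -> tuple[str, int, int] | None:
        """Comparator-species (chrom, start, end) or None when unliftable.

        The interval must lie within a single block that carries a row for
        ``species``; gap columns inside the interval shrink the lifted span.
        """
        for bstart, bend, block in self._by_chrom.get(chrom, []):
            if bstart <= start and end <= bend:
                ref = block.row_for(self.reference_species)
                other = block.row_for(species)
                if other is None:
                    return None
                if ref.strand != "+":
                    logger.warning("negative-strand reference row; lift skipped")
                    return None
                # columns holding the reference positions of the interval
                is_base = np.frombuffer(ref.text.encode(), dtype=np.uint8) != ord("-")
                cols = np.flatnonzero(is_base)
                col_start = int(cols[start - bstart])
                col_end = int(cols[end - bstart - 1]) + 1
                otext = other.text
                o_is_base = np.frombuffer(otext.encode(), dtype=np.uint8) != ord("-")
                before = int(o_is_base[:col_start].sum())
                inside = int(o_is_base[col_start:col_end].sum())
                if inside == 0:
                    return None  # entirely deleted in the comparator
                return (other.chromosome, other.start + before,
                        other.start + before + inside)
        return None


def _containing_gene(index: FeatureIndex, chrom: str, start: int, end: int
                     ) -> str | None:
    hits = index.genes_overlapping(chrom, start, end)
    return hits[0][2] if hits else None


def genic_orthology(
    uces: Sequence[UCERecord],
    index_a: FeatureIndex,
    index_b: FeatureIndex,
    orthologs_a: Mapping[str, str],
    orthologs_b: Mapping[str, str],
    lifter: MafLifter,
    species_b: str,
    x_chromosomes: frozenset[str] = frozenset({"X", "chrX"}),
) -> dict:
    """Fraction of UCE-containing genes sharing an orthogroup with species B.

    Reported separately for autosomes and X.  Genes whose UCEs cannot be
    lifted, or with no resolvable gene/orthogroup on either side, are
    excluded from the denominator as missing data.
    """
    gene_status: dict[str, tuple[bool | None, bool]] = {}  # gene -> (match, is_x)
    for rec in uces:
        gene_a = _containing_gene(index_a, rec.chromosome, rec.start, rec.end)
        if gene_a is None:
            continue
        if gene_a in gene_status and gene_status[gene_a][0] is not None:
            continue
        is_x = rec.chromosome in x_chromosomes
        lifted = lifter.lift(rec.chromosome, rec.start, rec.end, species_b)
        if lifted is None:
            gene_status.setdefault(gene_a, (None, is_x))
            continue
        gene_b = _containing_gene(index_b, *lifted)
        og_a = orthologs_a.get(gene_a)
        og_b = orthologs_b.get(gene_b) if gene_b else None
        if og_a is None or og_b is None:
            gene_status.setdefault(gene_a, (None, is_x))
            continue
        gene_status[gene_a] = (og_a == og_b, is_x)

    out = {}
    for label, want_x in (("autosomes", False), ("X", True)):
        vals = [m for m, is_x in gene_status.values() if is_x == want_x]
        resolved = [m for m in vals if m is not None]
        out[label] = {
            "n_genes": len(vals),
            "n_resolved": len(resolved),
            "n_matching": sum(resolved),
            "fraction_matching": (sum(resolved) / len(resolved)) if resolved else None,
        }
    return out


def flank_synteny(
    intergenic_uces: Sequence[UCERecord],
    index_a: FeatureIndex,
    index_b: FeatureIndex,
    orthologs_a: Mapping[str, str],
    orthologs_b: Mapping[str, str],
    lifter: MafLifter,
    species_b: str,
    species_a: str = "ref",
) -> tuple[list[SyntenyCall], dict]:
    """Classify each intergenic UCE into the six flank-orthology categories.

    A flank's status is *match* when its orthogroup appears among the
    comparator flanks' orthogroups at the lifted position, *nomatch* when
    both orthogroups resolve but differ, and *missing* when any link in
    the chain (lift, flanking gene, orthogroup entry) is absent.  A UCE
    lifted into an annotated gene of species B (intergenic in A) is an
    annotation disagreement: both flanks are called nomatch.
    """
    flanks_a = flanking_genes(intergenic_uces, index_a)
    calls: list[SyntenyCall] = []
    pair = (species_a, species_b)
    for rec in intergenic_uces:
        up_a, down_a = flanks_a[rec.id]
        lifted = lifter.lift(rec.chromosome, rec.start, rec.end, species_b)
        if lifted is None:
            calls.append(SyntenyCall(rec.id, "both_missing", pair))
            continue
        if _containing_gene(index_b, *lifted) is not None:
            logger.info("%s: genic in %s but intergenic in %s", rec.id,
                        species_b, species_a)
            calls.append(SyntenyCall(rec.id, "both_nomatch", pair))
            continue
        chrom_b, start_b, end_b = lifted
        glist = index_b.genes.get(chrom_b, [])
        up_b = max((g for g in glist if g[1] <= start_b), default=None,
                   key=lambda g: g[1])
        down_b = min((g for g in glist if g[0] >= end_b), default=None,
                     key=lambda g: g[0])
        b_ogs = {orthologs_b.get(g[2]) for g in (up_b, down_b) if g is not None}
        b_ogs.discard(None)

        statuses = []
        for gene_a in (up_a, down_a):
            og_a = orthologs_a.get(gene_a) if gene_a else None
            if og_a is None or not b_ogs:
                statuses.append("missing")
            elif og_a in b_ogs:
                statuses.append("match")
            else:
                statuses.append("nomatch")
        calls.append(SyntenyCall(rec.id, _category(statuses), pair))

    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    with_data = len(calls) - counts["both_missing"]
    full_or_half = (counts["both_flanks_match"] + counts["one_match_one_nomatch"]
                    + counts["one_match_one_missing"])
    summary = {
        "counts": counts,
        "n_uces": len(calls),
        "full_or_half_fraction": (full_or_half / with_data) if with_data else None,
    }
    return calls, summary


def _category(statuses: list[str]) -> str:
    s = sorted(statuses)
    if s == ["match", "match"]:
        return "both_flanks_match"
    if s == ["match", "nomatch"]:
        return "one_match_one_nomatch"
    if s == ["match", "missing"]:
        return "one_match_one_missing"
    if s == ["missing", "nomatch"]:
        return "one_nomatch_one_missing"
    if s == ["missing", "missing"]:
        return "both_missing"
    return "both_nomatch"
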