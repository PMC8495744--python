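"""Genomic-context classification of intervals against a GFF3 annotation.

Per-base classes form a partition of the genome:
``exon > five_prime_utr > three_prime_utr > intron > rna_gene`` take
priority in that order wherever overlapping isoforms disagree; everything
else is ``intergenic``.  Introns are derived as gene span minus the union
of exon and UTR features.  Intervals overlapping a gene span at all are
*genic* (the partly-or-wholly-within rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import numpy as np
from scipy import stats as sps

from .discovery import UCERecord
from .stats import control_ttest

__all__ = [
    "CLASSES",
    "FeatureIndex",
    "LocationProfile",
    "build_feature_index",
    "classify_interval",
    "annotate_records",
    "composition_summary",
    "at_content",
    "length_periodicity",
]

logger = logging.getLogger(__name__)

# ascending priority (later wins a contested base); intergenic is the default
_PRIORITY = ["rna_gene", "intron", "three_prime_utr", "five_prime_utr", "exon"]
CLASSES = ["exon", "five_prime_utr", "three_prime_utr", "intron", "rna_gene",
           "intergenic"]

_GFF_CLASS = {
    "exon": "exon",
    "five_prime_UTR": "five_prime_utr",
    "three_prime_UTR": "three_prime_utr",
}
_RNA_GENE_TYPES = {"ncRNA_gene", "rRNA_gene", "tRNA_gene", "snRNA_gene",
                   "miRNA_gene", "pseudogene"}
_GENE_TYPES = {"gene"} | _RNA_GENE_TYPES


@dataclass
class FeatureIndex:
    """Sorted, merged interval arrays per chromosome and class."""

    source: str
    # chrom -> class -> (starts, ends) as int64 arrays, 0-based half-open
    intervals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    # chrom -> gene list [(start, end, gene_id, is_rna)]
    genes: dict[str, list[tuple[int, int, str, bool]]]

    def chromosomes(self) -> list[str]:
        return sorted(self.intervals)

    def class_intervals(self, chrom: str, cls: str) -> tuple[np.ndarray, np.ndarray]:
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return self.intervals.get(chrom, {}).get(cls, empty)

    def overlapping(self, chrom: str, start: int, end: int, cls: str
                    ) -> list[tuple[int, int]]:
        """Intervals of ``cls`` overlapping [start, end): binary search + scan."""
        starts, ends = self.class_intervals(chrom, cls)
        if starts.size == 0:
            return []
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [(int(starts[i]), int(ends[i])) for i in range(lo, hi)]

    def genes_overlapping(self, chrom: str, start: int, end: int
                          ) -> list[tuple[int, int, str, bool]]:
        return [g for g in self.genes.get(chrom, [])
                if g[0] < end and g[1] > start]

    def gene_spans(self) -> dict[str, tuple[str, int, int]]:
        """gene_id -> (chrom, start, end)."""
        out = {}
        for chrom, glist in self.genes.items():
            for s, e, gid, _ in glist:
                out[gid] = (chrom, s, e)
        return out

    def class_base_totals(self) -> dict[str, int]:
        """Genome-wide per-class base counts under the priority partition.

        ``intergenic`` is excluded (its extent depends on chromosome
        lengths, which a GFF does not declare).
        """
        totals = {c: 0 for c in CLASSES if c != "intergenic"}
        for chrom in self.intervals:
            hi = max((int(e[-1]) for _, (s, e) in self.intervals[chrom].items()
                      if e.size), default=0)
            if hi == 0:
                continue
            codes = _paint(self, chrom, 0, hi)
            for ci, cls in enumerate(_PRIORITY, start=1):
                totals[cls] += int((codes == ci).sum())
        return totals


@dataclass
class LocationProfile:
    fractions: dict[str, float]
    junction_flags: set[str] = field(default_factory=set)
    genic: bool = False

    @property
    def dominant_class(self) -> str:
        return max(self.fractions.items(), key=lambda kv: (kv[1], kv[0]))[0]


def _merge(pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pairs.sort()
    starts, ends = [pairs[0][0]], [pairs[0][1]]
    for s, e in pairs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def build_feature_index(gff_path: str) -> FeatureIndex:
    """Ingest a GFF3 and derive the per-class interval sets.

    Intron intervals are computed as each gene's span minus the union of
    its exon/UTR children; children poking outside their parent span are
    clipped with a warning.
    """
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {}
    genes: dict[str, list[tuple[int, int, str, bool]]] = {}

    def add(chrom: str, cls: str, start: int, end: int) -> None:
        raw.setdefault(chrom, {}).setdefault(cls, []).append((start, end))

    for feat in db.all_features():
        if feat.featuretype not in _GENE_TYPES:
            continue
        gstart, gend = feat.start - 1, feat.end  # to 0-based half-open
        is_rna = feat.featuretype in _RNA_GENE_TYPES
        gid = feat.id
        genes.setdefault(feat.seqid, []).append((gstart, gend, gid, is_rna))
        if is_rna:
            add(feat.seqid, "rna_gene", gstart, gend)
            continue
        covered: list[tuple[int, int]] = []
        for child in db.children(gid):
            cls = _GFF_CLASS.get(child.featuretype)
            if cls is None:
                continue
            cs, ce = child.start - 1, child.end
            if cs < gstart or ce > gend:
                logger.warning(
                    "feature %s [%d,%d) outside parent %s [%d,%d); clipping",
                    child.id, cs, ce, gid, gstart, gend,
                )
                cs, ce = max(cs, gstart), min(ce, gend)
            if cs >= ce:
                continue
            add(feat.seqid, cls, cs, ce)
            covered.append((cs, ce))
        # introns: gene span minus exon/UTR union
        ms, me = _merge(covered)
        pos = gstart
        for s, e in zip(ms, me):
            if pos < s:
                add(feat.seqid, "intron", pos, int(s))
            pos = max(pos, int(e))
        if pos < gend:
            add(feat.seqid, "intron", pos, gend)

    intervals = {
        chrom: {cls: _merge(pairs) for cls, pairs in classes.items()}
        for chrom, classes in raw.items()
    }
    for chrom in genes:
        genes[chrom].sort()
        intervals.setdefault(chrom, {})
    return FeatureIndex(source=gff_path, intervals=intervals, genes=genes)


def _paint(index: FeatureIndex, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base class codes over [start, end): 0 = intergenic, 1.. = _PRIORITY."""
    codes = np.zeros(end - start, dtype=np.uint8)
    for ci, cls in enumerate(_PRIORITY, start=1):
        for s, e in index.overlapping(chrom, start, end, cls):
            codes[max(s, start) - start:min(e, end) - start] = ci
    return codes


def classify_interval(interval: tuple[str, int, int], index: FeatureIndex
                      ) -> LocationProfile:
    chrom, start, end = interval
    if chrom not in index.intervals and chrom not in index.genes:
        raise KeyError(f"chromosome {chrom!r} absent from feature index")
    if end <= start:
        raise ValueError("empty interval")
    codes = _paint(index, chrom, start, end)
    length = end - start
    names = ["intergenic"] + _PRIORITY
    fractions = {cls: 0.0 for cls in CLASSES}
    for code in range(len(names)):
        n = int((codes == code).sum())
        if n:
            fractions[names[code]] = n / length
    flags = set()
    change = np.flatnonzero(codes[1:] != codes[:-1])
    for i in change:
        a, b = names[codes[i]], names[codes[i + 1]]
        flags.add("-".join(sorted((_flag_name(a), _flag_name(b)))))
    genic = bool(index.genes_overlapping(chrom, start, end))
    return LocationProfile(fractions=fractions, junction_flags=flags, genic=genic)


def _flag_name(cls: str) -> str:
    return {"five_prime_utr": "utr", "three_prime_utr": "utr"}.get(cls, cls)


def annotate_records(records: Sequence[UCERecord], index: FeatureIndex
                     ) -> list[LocationProfile]:
    """Classify each record and set its genic/intergenic location_class."""
    profiles = []
    for rec in records:
        prof = classify_interval(rec.interval, index)
        rec.location_class = "genic" if prof.genic else "intergenic"
        profiles.append(prof)
    return profiles


def _set_fractions(intervals: Iterable[tuple[str, int, int]], index: FeatureIndex
                   ) -> dict[str, float]:
    """Base-weighted class composition of a set of intervals."""
    totals = {cls: 0 for cls in CLASSES}
    names = ["intergenic"] + _PRIORITY
    n_bases = 0
    for chrom, start, end in intervals:
        codes = _paint(index, chrom, start, end)
        n_bases += end - start
        for code in range(len(names)):
            totals[names[code]] += int((codes == code).sum())
    if n_bases == 0:
        raise ValueError("no bases to classify")
    return {cls: totals[cls] / n_bases for cls in CLASSES}


def composition_summary(
    records: Sequence[UCERecord],
    control_sets: Sequence[Sequence[tuple[str, int, int]]],
    index: FeatureIndex,
) -> dict:
    """Per-class UCE fraction vs control mean ± SD with a two-sided t-test.

    With fewer than two control sets the dispersion is undefined and
    p-values are omitted with a warning.
    """
    uce_frac = _set_fractions([r.interval for r in records], index)
    control_fracs = [_set_fractions(cs, index) for cs in control_sets]
    if len(control_sets) < 2:
        logger.warning("only %d control set(s): p-values omitted", len(control_sets))
    out = {}
    for cls in CLASSES:
        cvals = [cf[cls] for cf in control_fracs]
        mean, sd, p = control_ttest(uce_frac[cls], cvals) if cvals else (float("nan"), float("nan"), None)
        out[cls] = {
            "uce_fraction": uce_frac[cls],
            "control_mean": mean,
            "control_sd": sd,
            "p_value": p if len(control_sets) >= 2 else None,
        }
    return out


def at_content(records: Sequence[UCERecord]) -> float:
    if not records:
        raise ValueError("empty record list")
    at = total = 0
    for r in records:
        seq = r.sequence.upper()
        at += seq.count("A") + seq.count("T")
        total += len(seq)
    return at / total


def length_periodicity(records: Sequence[UCERecord]) -> dict:
    """Counts of lengths by residue mod 3 plus a chi-square against uniform."""
    if not records:
        raise ValueError("empty record list")
    counts = [0, 0, 0]
    for r in records:
        counts[r.length % 3] += 1
    chi2, p = sps.chisquare(counts)
    return {"counts_mod3": counts, "chi2": float(chi2), "p_value": float(p)}
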