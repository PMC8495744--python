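"""Per-interval diversity statistics (S, π, Tajima's D) from a VCF.

The VCF is loaded once into in-memory per-chromosome position/allele-count
arrays; interval queries are then binary searches, so no tabix index is
required.  Only SNP records are used.  Per site, with allele counts
``c_i`` over ``n`` called haplotypes, site heterozygosity is
``h = n/(n-1) * (1 - sum((c_i/n)^2))`` — exactly the mean pairwise
difference at the site — and π is the sum of ``h`` over sites divided by
the interval length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from .stats import paired_control_ttest

__all__ = [
    "TajimaConstants",
    "RegionDiversity",
    "VariantTable",
    "load_variant_table",
    "region_diversity",
    "diversity_comparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TajimaConstants:
    """Standard constants of Tajima's D for a sample of n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("need n >= 2 haplotypes")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1 = c1 / a1
        e2 = c2 / (a1 ** 2 + a2)
        return cls(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass
class RegionDiversity:
    chromosome: str
    start: int
    end: int
    n: int              # haplotype count used for the constants (region median)
    S: int
    pi: float           # per-site
    D: float | None     # None when S == 0 or n < 4
    snp_free: bool
    undefined: bool = False  # no site had >= 2 called haplotypes

    @property
    def length(self) -> int:
        return self.end - self.start


class VariantTable:
    """Per-chromosome sorted SNP arrays: position, allele counts, called n."""

    def __init__(self) -> None:
        self.pos: dict[str, np.ndarray] = {}
        # allele counts per site: (n_sites, max_alleles) padded with zeros
        self.counts: dict[str, np.ndarray] = {}
        self.n_called: dict[str, np.ndarray] = {}
        self.n_haplotypes: int = 0

    def sites_in(self, chrom: str, start: int, end: int) -> slice:
        pos = self.pos.get(chrom)
        if pos is None:
            return slice(0, 0)
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return slice(lo, hi)


def load_variant_table(vcf_path: str) -> VariantTable:
    """Read all SNP records (indels and other types skipped)."""
    table = VariantTable()
    vcf = VCF(vcf_path, gts012=False)
    table.n_haplotypes = 2 * len(vcf.samples)
    acc: dict[str, list[tuple[int, np.ndarray, int]]] = {}
    for rec in vcf:
        if not rec.is_snp:
            continue
        # genotype allele indices per haplotype; -1 = missing
        gts = np.asarray(rec.genotype.array())[:, :2].reshape(-1)
        called = gts[gts >= 0]
        n_alleles = 1 + len(rec.ALT)
        counts = np.bincount(called, minlength=n_alleles).astype(np.int64)
        acc.setdefault(rec.CHROM, []).append(
            (rec.POS - 1, counts, int(called.size))
        )
    for chrom, rows in acc.items():
        rows.sort(key=lambda r: r[0])
        max_alleles = max(r[1].size for r in rows)
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        counts = np.zeros((len(rows), max_alleles), dtype=np.int64)
        for i, (_, c, _) in enumerate(rows):
            counts[i, :c.size] = c
        table.pos[chrom] = pos
        table.counts[chrom] = counts
        table.n_called[chrom] = np.array([r[2] for r in rows], dtype=np.int64)
    return table


def region_diversity(table: VariantTable, interval: tuple[str, int, int]
                     ) -> RegionDiversity:
    """S, π, and Tajima's D for one interval.

    Sites with fewer than 2 called haplotypes are skipped.  D uses the
    per-region median called-haplotype count for its constants and is
    undefined (None) when S = 0.  π's denominator is the full interval
    length.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError("empty interval")
    sl = table.sites_in(chrom, start, end)
    counts = table.counts.get(chrom, np.zeros((0, 1), dtype=np.int64))[sl]
    n_called = table.n_called.get(chrom, np.zeros(0, dtype=np.int64))[sl]

    usable = n_called >= 2
    if counts.shape[0] > 0 and not usable.any():
        logger.warning("%s:%d-%d: no site with >= 2 called haplotypes", chrom, start, end)
        return RegionDiversity(chrom, start, end, n=0, S=0, pi=0.0, D=None,
                               snp_free=True, undefined=True)
    counts = counts[usable]
    n_called = n_called[usable]

    # segregating: >= 2 alleles observed among called genotypes
    seg = (counts > 0).sum(axis=1) >= 2
    S = int(seg.sum())
    if S == 0:
        return RegionDiversity(chrom, start, end,
                               n=int(np.median(n_called)) if n_called.size else 0,
                               S=0, pi=0.0, D=None, snp_free=True)
    c_seg = counts[seg]
    n_seg = n_called[seg]
    freqs_sq = (c_seg / n_seg[:, None]) ** 2
    h = (n_seg / (n_seg - 1)) * (1.0 - freqs_sq.sum(axis=1))
    pi_total = float(h.sum())
    length = end - start
    pi = pi_total / length

    n_region = int(np.median(n_seg))
    D: float | None = None
    if n_region >= 4:
        k = TajimaConstants.for_n(n_region)
        var = k.e1 * S + k.e2 * S * (S - 1)
        if var > 0:
            D = (pi_total - S / k.a1) / math.sqrt(var)
    return RegionDiversity(chrom, start, end, n=n_region, S=S, pi=pi, D=D,
                           snp_free=False)


def regions_diversity(table: VariantTable, intervals: Sequence[tuple[str, int, int]]
                      ) -> list[RegionDiversity]:
    return [region_diversity(table, iv) for iv in intervals]


def diversity_comparison(
    uce_stats: Sequence[RegionDiversity],
    control_stats: Sequence[Sequence[RegionDiversity]],
    labels: Mapping[tuple[str, int, int], tuple[str, str]] | None = None,
) -> dict:
    """Per-cell (arm × genic/intergenic) contrast table with paired t-tests.

    ``labels`` maps an interval to ``(location_class, arm)``; without it a
    single global cell is used.  Per statistic (S, π, D) the global test is
    a two-sided paired t-test pairing the UCE cell mean against the
    control-mean cell mean across cells.
    """
    if len(control_stats) < 2:
        raise ValueError("need >= 2 control sets for a dispersion estimate")

    def cell_of(rd: RegionDiversity) -> tuple[str, str]:
        if labels is None:
            return ("all", "all")
        return labels.get((rd.chromosome, rd.start, rd.end), ("unknown", rd.chromosome))

    def collect(stats: Sequence[RegionDiversity]) -> dict[tuple[str, str], dict[str, float]]:
        cells: dict[tuple[str, str], dict[str, list[float]]] = {}
        for rd in stats:
            c = cells.setdefault(cell_of(rd), {"S": [], "pi": [], "D": []})
            c["S"].append(float(rd.S))
            c["pi"].append(rd.pi)
            if rd.D is not None:
                c["D"].append(rd.D)
        return {
            cell: {k: (float(np.mean(v)) if v else float("nan"))
                   for k, v in vals.items()}
            for cell, vals in cells.items()
        }

    uce_cells = collect(uce_stats)
    control_cells = [collect(cs) for cs in control_stats]

    out: dict = {"cells": {}, "tests": {}}
    all_cells = sorted(uce_cells)
    for cell in all_cells:
        per_set = [cc.get(cell) for cc in control_cells]
        per_set = [c for c in per_set if c is not None]
        if not per_set:
            logger.warning("cell %s empty in all control sets; omitted", cell)
            continue
        entry = {}
        for stat in ("S", "pi", "D"):
            cvals = np.array([c[stat] for c in per_set])
            cvals = cvals[np.isfinite(cvals)]
            entry[stat] = {
                "uce_mean": uce_cells[cell][stat],
                "control_mean": float(cvals.mean()) if cvals.size else float("nan"),
                "control_sd": float(cvals.std(ddof=1)) if cvals.size > 1 else float("nan"),
            }
        out["cells"]["%s:%s" % (cell[1], cell[0])] = entry
    for stat in ("S", "pi", "D"):
        u = [uce_cells[c][stat] for c in all_cells]
        cm = []
        for c in all_cells:
            vals = [cc[c][stat] for cc in control_cells if c in cc]
            vals = [v for v in vals if math.isfinite(v)]
            cm.append(float(np.mean(vals)) if vals else float("nan"))
        out["tests"][stat] = paired_control_ttest(u, cm)
    out["n_snp_free"] = sum(1 for rd in uce_stats if rd.snp_free)
    out["n_regions"] = len(uce_stats)
    return out
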