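"""Matched random control interval sets.

Two match modes: ``maf_matched`` draws from the alignment coverage mask
(positions whose columns contain every required species), matching the
UCE length multiset; ``genome_matched`` draws from the whole genome,
additionally matching each UCE's genic/intergenic label.  Controls never
overlap UCEs or other controls of the same set; sets are independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation import FeatureIndex
from .discovery import UCERecord
from .mafio import AlignmentBlock

__all__ = [
    "ControlSet",
    "PlacementError",
    "build_coverage_mask",
    "mask_total",
    "sample_controls",
    "write_control_bed",
    "read_control_bed",
]

_MAX_REJECTIONS = 10_000


class PlacementError(RuntimeError):
    pass


@dataclass
class ControlSet:
    set_index: int
    match_mode: str  # "maf_matched" | "genome_matched"
    seed: int
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def lengths(self) -> list[int]:
        return sorted(e - s for _, s, e in self.intervals)


def build_coverage_mask(
    blocks: Iterable[AlignmentBlock],
    required_species: Sequence[str],
    reference_species: str,
) -> dict[str, list[tuple[int, int]]]:
    """Union of reference intervals whose columns are all eligible.

    Eligibility matches discovery: every required species present with an
    unambiguous base (gaps and Ns disqualify the column).
    """
    from .discovery import _column_masks  # same eligibility definition

    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for block in blocks:
        ref_row = block.row_for(reference_species)
        if ref_row is None:
            continue
        masks = _column_masks(block, list(required_species))
        if masks is None:
            continue
        eligible, _ = masks
        if not eligible.any():
            continue
        text = ref_row.text
        is_base = np.frombuffer(text.encode("ascii"), dtype=np.uint8) != ord("-")
        offset = np.cumsum(is_base) - 1
        padded = np.concatenate(([False], eligible, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for cs, ce in zip(starts, ends):
            first, last = int(offset[cs]), int(offset[ce - 1])
            if ref_row.strand == "+":
                ref_start = ref_row.start + first
                ref_end = ref_row.start + last + 1
            else:
                ref_start = ref_row.src_size - (ref_row.start + last + 1)
                ref_end = ref_row.src_size - (ref_row.start + first)
            per_chrom.setdefault(ref_row.chromosome, []).append((ref_start, ref_end))
    return {chrom: _merge(ivals) for chrom, ivals in per_chrom.items()}


def _merge(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    out: list[tuple[int, int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_total(mask: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for ivals in mask.values() for s, e in ivals)


class _OverlapTracker:
    """Per-chromosome occupied intervals with O(log n) overlap queries."""

    def __init__(self) -> None:
        self._ivals: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        import bisect
        lst = self._ivals.setdefault(chrom, [])
        bisect.insort(lst, (start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        import bisect
        lst = self._ivals.get(chrom)
        if not lst:
            return False
        i = bisect.bisect_left(lst, (start, start))
        if i < len(lst) and lst[i][0] < end:
            return True
        if i > 0 and lst[i - 1][1] > start:
            return True
        return False


def _is_genic(index: FeatureIndex, chrom: str, start: int, end: int) -> bool:
    return bool(index.genes_overlapping(chrom, start, end))


def sample_controls(
    uces: Sequence[UCERecord],
    *,
    mode: str,
    n_sets: int = 10,
    seed: int = 0,
    mask: dict[str, list[tuple[int, int]]] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    feature_index: FeatureIndex | None = None,
    arm_matched: bool = False,
) -> list[ControlSet]:
    """Draw ``n_sets`` independent matched control sets.

    Lengths are placed longest-first (placement order does not bias the
    conditional-uniform start distribution but sharply reduces rejection
    failures for long intervals).  Each set uses RNG stream
    ``default_rng([seed, set_index])``.
    """
    if mode not in ("maf_matched", "genome_matched"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "maf_matched":
        if mask is None:
            raise ValueError("maf_matched mode requires a coverage mask")
    else:
        if chrom_lengths is None or feature_index is None:
            raise ValueError("genome_matched mode requires chrom_lengths and feature_index")

    uce_tracker = _OverlapTracker()
    for r in uces:
        uce_tracker.add(r.chromosome, r.start, r.end)

    # (length, genic, chrom) per UCE; longest first
    jobs = []
    for r in uces:
        genic = None
        if mode == "genome_matched":
            genic = _is_genic(feature_index, r.chromosome, r.start, r.end)
        jobs.append((r.length, genic, r.chromosome))
    jobs.sort(key=lambda j: -j[0])

    sets: list[ControlSet] = []
    for set_index in range(1, n_sets + 1):
        rng = np.random.default_rng([seed, set_index])
        placed = _OverlapTracker()
        cs = ControlSet(set_index=set_index, match_mode=mode, seed=seed)
        for length, genic, chrom in jobs:
            if mode == "maf_matched":
                interval = _place_in_mask(rng, mask, length, uce_tracker, placed)
            else:
                lengths = ({chrom: chrom_lengths[chrom]} if arm_matched
                           else chrom_lengths)
                interval = _place_in_genome(
                    rng, lengths, length, genic, feature_index, uce_tracker, placed
                )
            placed.add(*interval)
            cs.intervals.append(interval)
        cs.intervals.sort()
        sets.append(cs)
    return sets


def _place_in_mask(rng, mask, length, uce_tracker, placed) -> tuple[str, int, int]:
    # positions where an interval of this length fits inside one mask interval
    slots = []  # (chrom, interval_start, n_starts)
    for chrom, ivals in mask.items():
        for s, e in ivals:
            n = e - s - length + 1
            if n > 0:
                slots.append((chrom, s, n))
    if not slots:
        raise PlacementError(f"no mask interval can hold length {length}")
    counts = np.array([n for _, _, n in slots], dtype=float)
    probs = counts / counts.sum()
    for _ in range(_MAX_REJECTIONS):
        k = int(rng.choice(len(slots), p=probs))
        chrom, s, n = slots[k]
        start = s + int(rng.integers(n))
        end = start + length
        if uce_tracker.overlaps(chrom, start, end) or placed.overlaps(chrom, start, end):
            continue
        return (chrom, start, end)
    raise PlacementError(
        f"exceeded {_MAX_REJECTIONS} rejections placing a length-{length} control"
    )


def _place_in_genome(rng, chrom_lengths, length, genic, index, uce_tracker, placed
                     ) -> tuple[str, int, int]:
    chroms = [c for c, L in chrom_lengths.items() if L >= length]
    if not chroms:
        raise PlacementError(f"no chromosome can hold length {length}")
    weights = np.array([chrom_lengths[c] - length + 1 for c in chroms], dtype=float)
    probs = weights / weights.sum()
    for _ in range(_MAX_REJECTIONS):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(chrom_lengths[chrom] - length + 1))
        end = start + length
        if _is_genic(index, chrom, start, end) != genic:
            continue
        if uce_tracker.overlaps(chrom, start, end) or placed.overlaps(chrom, start, end):
            continue
        return (chrom, start, end)
    raise PlacementError(
        f"exceeded {_MAX_REJECTIONS} rejections placing a length-{length} "
        f"{'genic' if genic else 'intergenic'} control"
    )


def write_control_bed(control_set: ControlSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(control_set.intervals, start=1):
            fh.write(f"{chrom}\t{start}\t{end}\tctrl{control_set.set_index}_{i}\t"
                     f"{end - start}\t+\n")


def read_control_bed(path: str, set_index: int = 0, mode: str = "unknown",
                     seed: int = 0) -> ControlSet:
    cs = ControlSet(set_index=set_index, match_mode=mode, seed=seed)
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            cs.intervals.append((f[0], int(f[1]), int(f[2])))
    return cs


def write_manifest(sets: Sequence[ControlSet], path: str) -> None:
    payload = {
        "n_sets": len(sets),
        "mode": sets[0].match_mode if sets else None,
        "seed": sets[0].seed if sets else None,
        "counts": [len(s.intervals) for s in sets],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
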