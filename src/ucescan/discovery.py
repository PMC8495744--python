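"""Ultraconserved-element discovery from multiple-alignment blocks.

A column is *eligible* when every required species contributes a row to
the block and carries an unambiguous base (A/C/G/T after uppercasing) in
that column — any gap or ambiguity code in any required row disqualifies
the column.  A column is *invariant* when all required rows carry the
identical base.  UCEs are maximal runs of >= ``min_run_length``
consecutive eligible, invariant columns; runs never span block
boundaries.  Coordinates are reported on the + strand of the reference,
0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

from .mafio import AlignmentBlock

__all__ = [
    "DiscoveryConfig",
    "UCERecord",
    "find_invariant_runs",
    "run_species_subset",
    "flag_repeats",
    "write_bed",
    "write_uce_table",
    "read_uce_table",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset(b"ACGT")
# byte-level lookup: maps A/C/G/T (upper or lower) to 0..3, everything else to 255
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase


class IntegrityError(RuntimeError):
    """UCE coordinates inconsistent with the reference sequence."""


@dataclass
class DiscoveryConfig:
    """Parameters for invariant-run discovery."""

    reference_species: str
    min_run_length: int = 18
    required_species: list[str] | None = None  # None: all species seen in the MAF

    def __post_init__(self) -> None:
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")
        if self.required_species is not None and self.reference_species not in self.required_species:
            raise ValueError("reference species must be among required_species")


@dataclass
class UCERecord:
    """One ultraconserved element in reference coordinates."""

    chromosome: str
    start: int          # 0-based inclusive
    end: int            # exclusive
    sequence: str       # uppercase, length == end - start
    species_set: str = "all"
    is_repeat: bool | None = None
    location_class: str | None = None
    id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            self.id = f"UCE_{self.chromosome}_{self.start}"
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != interval "
                f"length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start, self.end)


def _column_masks(
    block: AlignmentBlock, required: Sequence[str]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Return (eligible, invariant) boolean arrays over block columns.

    ``None`` when a required species is missing from the block (no column
    can then be eligible).
    """
    rows = []
    for sp in required:
        row = block.row_for(sp)
        if row is None:
            return None
        rows.append(np.frombuffer(row.text.encode("ascii"), dtype=np.uint8))
    enc = _ENC[np.vstack(rows)]  # (n_species, n_columns)
    eligible = (enc != 255).all(axis=0)
    invariant = (enc == enc[0]).all(axis=0)
    return eligible, eligible & invariant


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as (start, end) half-open."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def find_invariant_runs(
    blocks: Iterable[AlignmentBlock],
    config: DiscoveryConfig,
    species_set_label: str | None = None,
) -> list[UCERecord]:
    """Scan blocks for maximal invariant runs and lift them to the reference.

    Blocks that contain every other required species but lack the reference
    row are skipped with a warning: without a reference row the run cannot
    be assigned coordinates.
    """
    required = config.required_species
    ref_sp = config.reference_species
    records: list[UCERecord] = []
    label = species_set_label or (
        "all" if required is None else ",".join(sorted(required))
    )
    for block in blocks:
        req = sorted(block.species()) if required is None else list(required)
        ref_row = block.row_for(ref_sp)
        if ref_row is None:
            others = [sp for sp in req if sp != ref_sp]
            if all(block.row_for(sp) is not None for sp in others):
                logger.warning(
                    "block with all non-reference species but no reference row "
                    "(%s); skipped", ",".join(sorted(block.species()))
                )
            continue
        masks = _column_masks(block, req)
        if masks is None:
            continue
        _, ok = masks
        col_runs = _runs(ok, config.min_run_length)
        if not col_runs:
            continue
        text = ref_row.text
        # reference position of each column (strand-aware); eligible columns
        # are never gaps in the reference row.
        is_base = np.frombuffer(text.encode("ascii"), dtype=np.uint8) != ord("-")
        offset = np.cumsum(is_base) - 1  # ungapped index of each column
        for cs, ce in col_runs:
            seg = text[cs:ce].upper()
            assert "-" not in seg, "eligible columns cannot contain reference gaps"
            first = int(offset[cs])
            if ref_row.strand == "+":
                start = ref_row.start + first
                seq = seg
            else:
                # row text runs along the - strand; convert to + coordinates
                last = int(offset[ce - 1])
                start = ref_row.src_size - (ref_row.start + last + 1)
                seq = _revcomp(seg)
            records.append(
                UCERecord(
                    chromosome=ref_row.chromosome,
                    start=start,
                    end=start + (ce - cs),
                    sequence=seq,
                    species_set=label,
                )
            )
    records.sort(key=lambda r: (r.chromosome, r.start))
    return records


def run_species_subset(
    blocks: Iterable[AlignmentBlock],
    subset: Sequence[str],
    config: DiscoveryConfig,
    all_species: Sequence[str] | None = None,
) -> list[UCERecord]:
    """Discovery restricted to ``subset`` of species (same semantics)."""
    if not subset:
        raise ValueError("species subset must be non-empty")
    if all_species is not None:
        missing = sorted(set(subset) - set(all_species))
        if missing:
            raise ValueError(f"subset species not in MAF: {', '.join(missing)}")
    sub_cfg = DiscoveryConfig(
        reference_species=config.reference_species,
        min_run_length=config.min_run_length,
        required_species=list(subset),
    )
    return find_invariant_runs(blocks, sub_cfg)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def flag_repeats(records: list[UCERecord], reference_fasta: str | Fasta) -> list[UCERecord]:
    """Set ``is_repeat`` by exact whole-sequence occurrence counting.

    A record is a repeat when its sequence occurs >= 2 times in the
    reference, counting both strands; a position where a perfect
    palindrome matches itself via reverse complement counts once.
    """
    fasta = Fasta(reference_fasta) if isinstance(reference_fasta, str) else reference_fasta
    chroms = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    for rec in records:
        seq = rec.sequence.upper()
        rc = _revcomp(seq)
        fwd = sum(_count_overlapping(s, seq) for s in chroms.values())
        if fwd == 0:
            raise IntegrityError(
                f"{rec.id}: sequence not found in reference; coordinates "
                "inconsistent with FASTA"
            )
        if rc == seq:  # palindrome: rc occurrences are the same positions
            total = fwd
        else:
            total = fwd + sum(_count_overlapping(s, rc) for s in chroms.values())
        rec.is_repeat = total >= 2
    return records


def _count_overlapping(haystack: str, needle: str) -> int:
    return len(re.findall(f"(?={re.escape(needle)})", haystack))


# ---------------------------------------------------------------------------
# serialization

def write_bed(records: Sequence[UCERecord], path: str) -> None:
    """BED6: name = UCE id, score = length, strand = '+'."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.id}\t{r.length}\t+\n")


def write_uce_table(records: Sequence[UCERecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchromosome\tstart\tend\tlength\tsequence\tis_repeat\t"
                 "species_set\tlocation_class\n")
        for r in records:
            rep = "" if r.is_repeat is None else str(int(r.is_repeat))
            loc = r.location_class or ""
            fh.write(f"{r.id}\t{r.chromosome}\t{r.start}\t{r.end}\t{r.length}\t"
                     f"{r.sequence}\t{rep}\t{r.species_set}\t{loc}\n")


def read_uce_table(path: str) -> list[UCERecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rec = UCERecord(
                chromosome=f[idx["chromosome"]],
                start=int(f[idx["start"]]),
                end=int(f[idx["end"]]),
                sequence=f[idx["sequence"]],
                species_set=f[idx["species_set"]],
                id=f[idx["id"]],
            )
            rep = f[idx["is_repeat"]]
            rec.is_repeat = bool(int(rep)) if rep else None
            rec.location_class = f[idx["location_class"]] or None
            records.append(rec)
    return records


def total_invariant_bases(records: Sequence[UCERecord]) -> int:
    return sum(r.length for r in records)


def per_chromosome_counts(records: Sequence[UCERecord]) -> dict[str, dict[str, int]]:
    """Per-chromosome UCE count and invariant-base total (Table-1 shape)."""
    out: dict[str, dict[str, int]] = {}
    for r in records:
        d = out.setdefault(r.chromosome, {"n_uces": 0, "invariant_bases": 0})
        d["n_uces"] += 1
        d["invariant_bases"] += r.length
    return out
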