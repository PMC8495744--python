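"""MAF (Multiple Alignment Format) block model and I/O.

Blocks are stored as lightweight dataclasses.  Row coordinates follow the
MAF convention: ``start`` is 0-based on the + strand of the source for
``strand == '+'`` rows, and on the reverse-complemented source for
``strand == '-'`` rows; ``size`` is the ungapped length of the row text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = ["MafRow", "AlignmentBlock", "MafParseError", "read_maf", "write_maf"]

GAP = "-"
_VALID_STRANDS = {"+", "-"}


class MafParseError(ValueError):
    """Malformed MAF input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class MafRow:
    """One 's' line of a MAF block."""

    src: str                # e.g. "species.chrom"
    start: int              # 0-based, strand-relative (MAF convention)
    size: int               # ungapped length
    strand: str             # '+' or '-'
    src_size: int           # length of the whole source sequence
    text: str               # aligned text with '-' gaps

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chromosome(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]

    def plus_start(self) -> int:
        """Start on the + strand of the source, regardless of row strand."""
        if self.strand == "+":
            return self.start
        return self.src_size - (self.start + self.size)

    def plus_end(self) -> int:
        return self.plus_start() + self.size


@dataclass
class AlignmentBlock:
    """One MAF alignment block: per-species rows over identical column count."""

    rows: list[MafRow] = field(default_factory=list)
    score: float | None = None

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def species(self) -> set[str]:
        return {r.species for r in self.rows}

    def row_for(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None

    def validate(self) -> None:
        ncol = self.n_columns
        for r in self.rows:
            if len(r.text) != ncol:
                raise MafParseError(
                    f"row {r.src}: text length {len(r.text)} != block width {ncol}"
                )
            ungapped = len(r.text) - r.text.count(GAP)
            if ungapped != r.size:
                raise MafParseError(
                    f"row {r.src}: declared size {r.size} != ungapped length {ungapped}"
                )


def read_maf(path_or_handle: str | TextIO) -> Iterator[AlignmentBlock]:
    """Stream :class:`AlignmentBlock` objects from a MAF file in file order.

    Raises :class:`MafParseError` with a line number on malformed rows.
    """
    if isinstance(path_or_handle, str):
        handle: TextIO = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
        close = False
    try:
        yield from _parse(handle)
    finally:
        if close:
            handle.close()


def _parse(handle: TextIO) -> Iterator[AlignmentBlock]:
    block: AlignmentBlock | None = None
    block_line = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if block is not None:
                _finish(block, block_line)
                yield block
                block = None
            continue
        if line.startswith("#"):
            continue
        if line.startswith("a"):
            if block is not None:
                _finish(block, block_line)
                yield block
            score = None
            for tok in line.split()[1:]:
                if tok.startswith("score="):
                    try:
                        score = float(tok[6:])
                    except ValueError as exc:
                        raise MafParseError(f"bad score field {tok!r}", lineno) from exc
            block = AlignmentBlock(score=score)
            block_line = lineno
        elif line.startswith("s"):
            if block is None:
                raise MafParseError("'s' line outside of a block", lineno)
            fields = line.split()
            if len(fields) != 7:
                raise MafParseError(
                    f"expected 7 fields in 's' line, got {len(fields)}", lineno
                )
            _, src, start, size, strand, src_size, text = fields
            if strand not in _VALID_STRANDS:
                raise MafParseError(f"bad strand {strand!r}", lineno)
            try:
                row = MafRow(src, int(start), int(size), strand, int(src_size), text)
            except ValueError as exc:
                raise MafParseError(f"non-integer coordinate field: {exc}", lineno) from exc
            ungapped = len(text) - text.count(GAP)
            if ungapped != row.size:
                raise MafParseError(
                    f"row {src}: declared size {row.size} != ungapped length {ungapped}",
                    lineno,
                )
            block.rows.append(row)
        # 'i', 'e', 'q' lines and anything else are ignored
    if block is not None:
        _finish(block, block_line)
        yield block


def _finish(block: AlignmentBlock, lineno: int) -> None:
    ncol = block.n_columns
    for r in block.rows:
        if len(r.text) != ncol:
            raise MafParseError(
                f"row {r.src}: text length {len(r.text)} != block width {ncol}", lineno
            )


def write_maf(blocks: Iterable[AlignmentBlock], path_or_handle: str | TextIO) -> None:
    """Write blocks to a ``##maf`` file."""
    if isinstance(path_or_handle, str):
        handle: TextIO = open(path_or_handle, "w")
        close = True
    else:
        handle = path_or_handle
        close = False
    try:
        handle.write("##maf version=1 scoring=none\n")
        for block in blocks:
            if block.score is not None:
                handle.write(f"a score={block.score:g}\n")
            else:
                handle.write("a\n")
            width = max((len(r.src) for r in block.rows), default=0)
            for r in block.rows:
                handle.write(
                    f"s {r.src:<{width}} {r.start:>10d} {r.size:>8d} {r.strand} "
                    f"{r.src_size:>10d} {r.text}\n"
                )
            handle.write("\n")
    finally:
        if close:
            handle.close()


def maf_to_string(blocks: Iterable[AlignmentBlock]) -> str:
    buf = io.StringIO()
    write_maf(blocks, buf)
    return buf.getvalue()
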