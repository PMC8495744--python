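"""PFM scanning with exact null p-values, BH q-values, and Cas9 site search.

Log-odds matrices are discretized (default 1/1000 bit per step) and the
exact null score distribution of a background k-mer is computed by
positionwise convolution, so every reported p-value is a lookup in an
exact tail table rather than an approximation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .stats import bh_fdr

__all__ = [
    "PFM",
    "ScoreTable",
    "read_jaspar",
    "pfm_to_pwm",
    "score_pvalue_table",
    "scan",
    "cas9_targets",
    "estimate_background",
]

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i

DEFAULT_GRANULARITY = 1.0 / 1000.0  # bits per discretization step
DEFAULT_PSEUDOCOUNT = 0.1
_MAX_TABLE_BINS = 10 ** 6


@dataclass
class PFM:
    id: str
    name: str
    counts: np.ndarray  # (4, w) rows A,C,G,T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"{self.id}: counts must be 4 x w with w >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.id}: column with no positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def read_jaspar(path: str) -> list[PFM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PFM(id=m.matrix_id or m.name, name=m.name, counts=counts))
    return out


def estimate_background(sequences: Mapping[str, str] | Sequence[str]) -> np.ndarray:
    """Base composition of the scanned set (add-one smoothed so every base
    has positive probability); uniform fallback when empty."""
    seqs = sequences.values() if isinstance(sequences, Mapping) else sequences
    counts = np.zeros(4)
    for seq in seqs:
        enc = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = enc[enc != 255]
        counts += np.bincount(valid, minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts += 1.0
    return counts / counts.sum()


def pfm_to_pwm(
    pfm: PFM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Log2-odds weights: log2(((c + pc*bg) / (colsum + pc)) / bg)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    return np.log2(probs / bg[:, None])


@dataclass
class ScoreTable:
    """Exact discretized null distribution of a motif score."""

    int_weights: np.ndarray  # (4, w) integer scores
    granularity: float
    min_score: int
    pmf: np.ndarray          # P(score == min_score + i)
    tail: np.ndarray         # P(score >= min_score + i)

    def pvalue(self, int_score: int) -> float:
        i = int_score - self.min_score
        if i < 0:
            return 1.0
        if i >= self.tail.size:
            return float(self.tail[-1]) if self.tail.size else 1.0
        return float(self.tail[i])


def score_pvalue_table(
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreTable:
    """Exact null distribution of the discretized score by DP over columns."""
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    iw = np.rint(pwm / granularity).astype(np.int64)
    col_min = iw.min(axis=0)
    col_max = iw.max(axis=0)
    span = int((col_max - col_min).sum()) + 1
    if span > _MAX_TABLE_BINS:
        raise ValueError(
            f"score table would need {span} bins (> {_MAX_TABLE_BINS}); "
            "use a coarser granularity"
        )
    min_score = int(col_min.sum())
    pmf = np.zeros(span)
    pmf[0] = 1.0
    reach = 1  # current occupied prefix length
    for j in range(iw.shape[1]):
        width = int(col_max[j] - col_min[j])
        new = np.zeros(reach + width)
        for b in range(4):
            off = int(iw[b, j] - col_min[j])
            new[off:off + reach] += bg[b] * pmf[:reach]
        reach += width
        pmf[:reach] = new
    pmf = pmf[:reach]
    tail = np.cumsum(pmf[::-1])[::-1]
    return ScoreTable(int_weights=iw, granularity=granularity,
                      min_score=min_score, pmf=pmf, tail=np.minimum(tail, 1.0))


_COMP_IDX = np.array([3, 2, 1, 0, 255], dtype=np.uint8)


def _window_scores(enc: np.ndarray, iw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus a validity mask (no ambiguous base)."""
    w = iw.shape[1]
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(enc == 255, 0, enc)
    for j in range(w):
        col = enc[j:j + n]
        valid &= col != 255
        scores += iw[safe[j:j + n], j]
    return scores, valid


def scan(
    sequences: Mapping[str, str],
    pfms: Sequence[PFM],
    q_threshold: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> tuple[pd.DataFrame, dict[str, bool], int]:
    """Scan both strands of every sequence at every offset.

    Returns ``(hits, has_hit, n_tests)``: hits passing the BH q-value
    threshold (q computed jointly over every scanned test in the run), a
    per-sequence any-hit flag, and the total number of tests performed.
    """
    if background is None:
        background = estimate_background(sequences)
    tables = {}
    for pfm in pfms:
        pwm = pfm_to_pwm(pfm, pseudocount, background)
        tables[pfm.id] = score_pvalue_table(pwm, background, granularity)

    rows = []   # (seq_id, motif_id, start, strand, score_bits, p)
    pvals = []
    for seq_id, seq in sequences.items():
        enc = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
        enc_rc = _COMP_IDX[np.where(enc == 255, 4, enc)][::-1]
        for pfm in pfms:
            table = tables[pfm.id]
            w = pfm.width
            if len(seq) < w:
                continue
            for strand, e in (("+", enc), ("-", enc_rc)):
                scores, valid = _window_scores(e, table.int_weights)
                for pos in np.flatnonzero(valid):
                    p = table.pvalue(int(scores[pos]))
                    start = int(pos) if strand == "+" else len(seq) - int(pos) - w
                    rows.append((seq_id, pfm.id, start, strand,
                                 float(scores[pos]) * table.granularity, p))
                    pvals.append(p)

    n_tests = len(pvals)
    has_hit = {seq_id: False for seq_id in sequences}
    if n_tests == 0:
        empty = pd.DataFrame(
            columns=["sequence_id", "motif_id", "start", "strand", "score", "p_value",
                     "q_value"]
        )
        return empty, has_hit, 0
    qvals = bh_fdr(np.asarray(pvals))
    df = pd.DataFrame(
        rows, columns=["sequence_id", "motif_id", "start", "strand", "score", "p_value"]
    )
    df["q_value"] = qvals
    hits = df[df["q_value"] < q_threshold].reset_index(drop=True)
    for seq_id in hits["sequence_id"].unique():
        has_hit[seq_id] = True
    return hits, has_hit, n_tests


def hit_fraction_summary(
    has_hit: Mapping[str, bool],
    labels: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Fraction of sequences with >= 1 hit, optionally split by (class, arm)."""
    total = len(has_hit)
    overall = sum(has_hit.values()) / total if total else float("nan")
    out = {"n_sequences": total, "fraction_with_hit": overall, "cells": {}}
    if labels:
        cells: dict[tuple[str, str], list[bool]] = {}
        for seq_id, flag in has_hit.items():
            if seq_id in labels:
                cells.setdefault(labels[seq_id], []).append(flag)
        out["cells"] = {
            f"{arm}:{cls}": sum(v) / len(v) for (cls, arm), v in sorted(cells.items())
        }
    return out


# ---------------------------------------------------------------------------
# Cas9 target search

_CAS9_FWD = re.compile(r"(?=[ACGT]{19}GG)")   # 18 bp + NGG, fully internal
_CAS9_REV = re.compile(r"(?=CC[ACGT]{19})")   # CCN + 18 bp


def has_cas9_site(sequence: str) -> bool:
    """True iff a fully internal Cas9 site exists (needs length >= 21)."""
    seq = sequence.upper()
    if len(seq) < 21:
        return False
    return bool(_CAS9_FWD.search(seq)) or bool(_CAS9_REV.search(seq))


def cas9_targets(records) -> tuple[dict[str, bool], dict]:
    """Per-record Cas9 suitability and counts; repeats reported separately."""
    flags = {r.id: has_cas9_site(r.sequence) for r in records}
    n_with = sum(flags.values())
    n_repeat_with = sum(
        1 for r in records if flags[r.id] and r.is_repeat
    )
    return flags, {
        "n_records": len(records),
        "n_with_target": n_with,
        "n_repeat_flagged_with_target": n_repeat_with,
        "n_unique_with_target": n_with - n_repeat_with,
    }
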