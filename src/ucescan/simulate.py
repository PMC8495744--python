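"""Synthetic fixture generator: alignments, annotations, variants, motifs.

Emits a reference FASTA, a MAF with per-species rows (gaps, dropout,
divergence structured by a phylogeny), a GFF3 of tiled gene models, a
many-sample VCF, a JASPAR PFM file, ortholog tables, and a GO assignment
table — all with planted ground truth so every downstream stage can be
validated against known answers.

Randomness is fully derived from ``config.seed``; each stage uses its own
substream so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from io import StringIO
from typing import Sequence

import numpy as np
from Bio import Phylo

from .mafio import AlignmentBlock, MafRow, write_maf

__all__ = [
    "SimulationConfig",
    "SimulatedGene",
    "simulate_reference",
    "simulate_alignment",
    "simulate_gene_models",
    "simulate_variants",
    "generate_pfms",
    "plant_motifs",
    "simulate_orthologs",
    "simulate_go_table",
    "simulate_all",
    "random_planted_elements",
    "harmonic_number",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}

# substream tags, one per stage
_S_REFERENCE, _S_ALIGNMENT, _S_GENES, _S_VARIANTS, _S_MOTIFS, _S_ORTHO, _S_GO = range(7)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 21
    tree: str | None = None          # newick; None -> star tree at `divergence`
    divergence: float = 0.2          # root-to-leaf length for the default tree
    genome_length: int = 100_000
    n_chromosomes: int = 1
    gap_open_prob: float = 0.02      # per species per block
    coverage_dropout_prob: float = 0.02
    gc_content: float = 0.5
    planted_elements: list[tuple[str, int, int]] = field(default_factory=list)
    n_haplotypes: int = 20
    theta_neutral: float = 0.01      # per-site scaled diversity outside elements
    theta_constrained: float = 0.0   # inside elements
    block_size_range: tuple[int, int] = (200, 2000)
    force_boundary_mismatch: bool = True
    missing_genotype_prob: float = 0.0
    # gene models
    n_genes: int = 20
    rna_gene_fraction: float = 0.1
    # motifs / orthologs / GO
    n_motifs: int = 5
    motif_plant_fraction: float = 0.5
    ortholog_mismatch_fraction: float = 0.0
    ortholog_missing_fraction: float = 0.0
    n_go_terms: int = 20

    reference_species: str = "ref"

    def species_names(self) -> list[str]:
        return [self.reference_species] + [
            f"sp{i:02d}" for i in range(1, self.n_species)
        ]

    def chromosome_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lengths = {}
        for i in range(self.n_chromosomes):
            name = f"chr{i + 1}"
            lengths[name] = base
        # remainder on the last chromosome
        lengths[f"chr{self.n_chromosomes}"] += self.genome_length - base * self.n_chromosomes
        return lengths

    def validate(self) -> None:
        for p in (self.gap_open_prob, self.coverage_dropout_prob, self.gc_content,
                  self.motif_plant_fraction, self.ortholog_mismatch_fraction,
                  self.ortholog_missing_fraction, self.missing_genotype_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.theta_neutral < 0 or self.theta_constrained < 0:
            raise SimulationError("theta must be non-negative")
        if self.n_haplotypes < 2:
            raise SimulationError("need at least 2 haplotypes")
        lengths = self.chromosome_lengths()
        total_planted = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, length in self.planted_elements:
            if chrom not in lengths:
                raise SimulationError(f"planted element on unknown chromosome {chrom}")
            if start < 0 or start + length > lengths[chrom]:
                raise SimulationError(
                    f"planted element {chrom}:{start}+{length} outside chromosome"
                )
            by_chrom.setdefault(chrom, []).append((start, start + length))
            total_planted += length
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise SimulationError(
                        f"planted elements overlap on {chrom}: [{s1},{e1}) and [{s2},{e2})"
                    )
        if total_planted > self.genome_length:
            raise SimulationError("genome shorter than total planted length")

    def planted_intervals(self) -> list[tuple[str, int, int]]:
        """(chrom, start, end) sorted."""
        out = [(c, s, s + l) for c, s, l in self.planted_elements]
        out.sort()
        return out


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def harmonic_number(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i for a sample of n haplotypes."""
    return float(sum(1.0 / i for i in range(1, n)))


# ---------------------------------------------------------------------------
# phylogeny

def species_divergences(config: SimulationConfig) -> dict[str, float]:
    """Root-to-leaf path length per species (expected substitutions/site)."""
    names = config.species_names()
    if config.tree is None:
        return {sp: (0.0 if sp == config.reference_species else config.divergence)
                for sp in names}
    tree = Phylo.read(StringIO(config.tree), "newick")
    leaves = tree.get_terminals()
    if len(leaves) != config.n_species:
        raise SimulationError(
            f"tree has {len(leaves)} leaves, config expects {config.n_species}"
        )
    depths = tree.depths()
    out = {leaf.name: float(depth) for leaf, depth in depths.items()
           if leaf.is_terminal()}
    missing = set(names) - set(out)
    if missing:
        raise SimulationError(f"tree lacks leaves for species: {sorted(missing)}")
    return {sp: out[sp] for sp in names}


# ---------------------------------------------------------------------------
# reference genome

def simulate_reference(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Reference chromosomes as uint8 base codes (0..3 = A,C,G,T)."""
    config.validate()
    rng = _rng(config, _S_REFERENCE)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        chrom: rng.choice(4, size=length, p=probs).astype(np.uint8)
        for chrom, length in config.chromosome_lengths().items()
    }


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


_DECODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _DECODE_TABLE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3 (anything else -> 255)."""
    return _DECODE_TABLE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def write_fasta(chroms: dict[str, np.ndarray | str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            text = seq if isinstance(seq, str) else decode(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(text), width):
                fh.write(text[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# alignment

def simulate_alignment(
    config: SimulationConfig,
    reference: dict[str, np.ndarray] | None = None,
) -> tuple[list[AlignmentBlock], dict[str, np.ndarray]]:
    """Emit MAF blocks partitioning the reference.

    Within planted elements every species row equals the reference (no
    substitutions, gaps, or dropout).  Outside, each non-reference row
    mutates each site independently with probability ``1 - exp(-d)`` where
    ``d`` is the species' root-to-leaf path length; mutated bases are drawn
    uniformly from the three alternatives.  Blocks never split a planted
    element.  When ``force_boundary_mismatch`` is set, the columns directly
    flanking each planted element carry at least one substitution, making
    planted-truth recovery exact rather than probabilistic.
    """
    config.validate()
    if reference is None:
        reference = simulate_reference(config)
    rng = _rng(config, _S_ALIGNMENT)
    divergences = species_divergences(config)
    species = config.species_names()
    nonref = [sp for sp in species if sp != config.reference_species]
    p_mut = {sp: 1.0 - math.exp(-divergences[sp]) for sp in nonref}
    lo, hi = config.block_size_range

    planted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in config.planted_intervals():
        planted_by_chrom.setdefault(chrom, []).append((s, e))

    blocks: list[AlignmentBlock] = []
    for chrom, codes in reference.items():
        length = len(codes)
        elements = planted_by_chrom.get(chrom, [])
        planted_mask = np.zeros(length, dtype=bool)
        boundary = set()
        for s, e in elements:
            planted_mask[s:e] = True
            if s - 1 >= 0:
                boundary.add(s - 1)
            if e < length:
                boundary.add(e)
        # per-species start offsets in their own (synthetic) genomes
        offsets = {sp: 0 for sp in nonref}
        rows_by_species: dict[str, list[MafRow]] = {sp: [] for sp in nonref}
        chrom_blocks: list[AlignmentBlock] = []

        pos = 0
        while pos < length:
            end = min(pos + int(rng.integers(lo, hi + 1)), length)
            for s, e in elements:  # never split a planted element
                if s < end < e:
                    end = e
                    break
            ncol = end - pos
            seg = codes[pos:end]
            pmask = planted_mask[pos:end]
            overlaps_planted = bool(pmask.any())

            present = []
            for sp in nonref:
                if not overlaps_planted and rng.random() < config.coverage_dropout_prob:
                    offsets[sp] += ncol  # unaligned, but the sequence exists
                else:
                    present.append(sp)

            # substitution masks for all present species, then enforce
            # boundary mismatches before building row text
            mut = np.zeros((len(present), ncol), dtype=bool)
            for i, sp in enumerate(present):
                m = rng.random(ncol) < p_mut[sp]
                m &= ~pmask
                mut[i] = m
            if config.force_boundary_mismatch and present:
                for b in boundary:
                    if pos <= b < end:
                        j = b - pos
                        if not mut[:, j].any():
                            mut[int(rng.integers(len(present))), j] = True

            block = AlignmentBlock()
            block.rows.append(MafRow(
                src=f"{config.reference_species}.{chrom}",
                start=pos, size=ncol, strand="+", src_size=length,
                text=decode(seg),
            ))
            for i, sp in enumerate(present):
                derived = seg.copy()
                m = mut[i]
                n_mut = int(m.sum())
                if n_mut:
                    derived[m] = (derived[m] + 1 + rng.integers(0, 3, size=n_mut)) % 4
                text = decode(derived)
                if rng.random() < config.gap_open_prob:
                    text = _open_gap(text, pmask, rng)
                ungapped = ncol - text.count("-")
                row = MafRow(
                    src=f"{sp}.{chrom}", start=offsets[sp], size=ungapped,
                    strand="+", src_size=0, text=text,
                )
                block.rows.append(row)
                rows_by_species[sp].append(row)
                offsets[sp] += ungapped
            chrom_blocks.append(block)
            pos = end

        for sp in nonref:  # patch per-species source sizes now totals are known
            total = offsets[sp]
            for row in rows_by_species[sp]:
                row.src_size = total
        blocks.extend(chrom_blocks)
    return blocks, reference


def _open_gap(text: str, planted_mask: np.ndarray, rng: np.random.Generator) -> str:
    """Replace a short stretch with gap characters, avoiding planted columns."""
    candidates = np.flatnonzero(~planted_mask)
    if candidates.size == 0:
        return text
    start = int(rng.choice(candidates))
    max_len = min(int(rng.geometric(0.4)), 10)
    chars = list(text)
    for j in range(start, min(start + max_len, len(chars))):
        if planted_mask[j]:
            break
        chars[j] = "-"
    return "".join(chars)


def random_planted_elements(
    config: SimulationConfig,
    n: int,
    length_range: tuple[int, int] = (18, 164),
    min_gap: int = 20,
) -> list[tuple[str, int, int]]:
    """Draw n non-overlapping (chrom, start, length) tuples, deterministic in seed."""
    rng = np.random.default_rng([config.seed, 99])
    lengths = config.chromosome_lengths()
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[tuple[str, int, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n + 10_000:
            raise SimulationError("could not place planted elements without overlap")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if lengths[chrom] <= length + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap, lengths[chrom] - length - min_gap))
        ok = all(start + length + min_gap <= s or start >= e + min_gap
                 for s, e in placed[chrom])
        if ok:
            placed[chrom].append((start, start + length))
            out.append((chrom, start, length))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# gene models

@dataclass
class SimulatedGene:
    id: str
    chrom: str
    start: int      # 0-based half-open span
    end: int
    strand: str
    is_rna: bool
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def simulate_gene_models(
    config: SimulationConfig,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SimulatedGene]:
    """Place non-overlapping gene models; raises when density is too high."""
    rng = _rng(config, _S_GENES)
    if chrom_lengths is None:
        chrom_lengths = config.chromosome_lengths()
    cursors = {c: 0 for c in chrom_lengths}
    chroms = list(chrom_lengths)
    genes: list[SimulatedGene] = []
    for gi in range(config.n_genes):
        is_rna = rng.random() < config.rna_gene_fraction
        if is_rna:
            span = int(rng.integers(80, 400))
            parts = None
        else:
            n_exons = int(rng.integers(1, 5))
            utr5 = int(rng.integers(20, 101))
            utr3 = int(rng.integers(20, 101))
            exons = [int(rng.integers(100, 301)) for _ in range(n_exons)]
            introns = [int(rng.integers(50, 201)) for _ in range(n_exons - 1)]
            span = utr5 + utr3 + sum(exons) + sum(introns)
            parts = (utr5, exons, introns, utr3)
        placed = False
        order = list(rng.permutation(len(chroms)))
        for ci in order:
            chrom = chroms[ci]
            gap = int(rng.integers(100, 600))
            start = cursors[chrom] + gap
            if start + span <= chrom_lengths[chrom]:
                cursors[chrom] = start + span
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"gene density too high: could not place gene {gi + 1}/{config.n_genes}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene = SimulatedGene(
            id=f"G{gi + 1:05d}", chrom=chrom, start=start, end=start + span,
            strand=strand, is_rna=is_rna,
        )
        if parts is not None:
            utr5, exons, introns, utr3 = parts
            pos = start
            left_utr = utr5 if strand == "+" else utr3
            right_utr = utr3 if strand == "+" else utr5
            left = (pos, pos + left_utr)
            pos += left_utr
            for k, ex in enumerate(exons):
                gene.exons.append((pos, pos + ex))
                pos += ex
                if k < len(introns):
                    pos += introns[k]
            right = (pos, pos + right_utr)
            pos += right_utr
            assert pos == gene.end
            if strand == "+":
                gene.utr5, gene.utr3 = left, right
            else:
                gene.utr3, gene.utr5 = left, right
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(genes: Sequence[SimulatedGene], path: str) -> None:
    """GFF3, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.start + 1, g.end
            if g.is_rna:
                fh.write(f"{g.chrom}\tsim\tncRNA_gene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                         f"ID={g.id}\n")
                fh.write(f"{g.chrom}\tsim\tncRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                         f"ID={g.id}.t1;Parent={g.id}\n")
                continue
            fh.write(f"{g.chrom}\tsim\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.id}\n")
            fh.write(f"{g.chrom}\tsim\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                     f"ID={g.id}.t1;Parent={g.id}\n")
            if g.utr5:
                fh.write(f"{g.chrom}\tsim\tfive_prime_UTR\t{g.utr5[0] + 1}\t{g.utr5[1]}"
                         f"\t.\t{g.strand}\t.\tID={g.id}.u5;Parent={g.id}.t1\n")
            for k, (es, ee) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                         f"ID={g.id}.e{k};Parent={g.id}.t1\n")
            if g.utr3:
                fh.write(f"{g.chrom}\tsim\tthree_prime_UTR\t{g.utr3[0] + 1}\t{g.utr3[1]}"
                         f"\t.\t{g.strand}\t.\tID={g.id}.u3;Parent={g.id}.t1\n")


# ---------------------------------------------------------------------------
# variants

def simulate_variants(
    config: SimulationConfig,
    reference: dict[str, np.ndarray],
    path: str,
) -> int:
    """Write a sorted biallelic-SNP VCF; returns the number of records.

    Sites are a Bernoulli thinning with per-site probability
    ``theta * a1(n)`` (Watterson's identity for expected segregating
    sites), using ``theta_constrained`` inside planted elements.  Derived
    allele counts follow the neutral site-frequency spectrum (P(i) ∝ 1/i).
    """
    config.validate()
    rng = _rng(config, _S_VARIANTS)
    n_hap = config.n_haplotypes
    if n_hap % 2:
        raise SimulationError("n_haplotypes must be even (diploid samples)")
    a1 = harmonic_number(n_hap)
    sfs = np.array([1.0 / i for i in range(1, n_hap)])
    sfs /= sfs.sum()

    planted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in config.planted_intervals():
        planted_by_chrom.setdefault(chrom, []).append((s, e))

    n_samples = n_hap // 2
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    n_records = 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ucescan-simulate\n")
        for chrom, codes in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(codes)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, codes in reference.items():
            length = len(codes)
            rate = np.full(length, config.theta_neutral * a1)
            for s, e in planted_by_chrom.get(chrom, []):
                rate[s:e] = config.theta_constrained * a1
            sites = np.flatnonzero(rng.random(length) < rate)
            for pos in sites:
                ref_code = int(codes[pos])
                alt_code = (ref_code + 1 + int(rng.integers(0, 3))) % 4
                count = 1 + int(rng.choice(n_hap - 1, p=sfs))
                carriers = rng.choice(n_hap, size=count, replace=False)
                hap = np.zeros(n_hap, dtype=int)
                hap[carriers] = 1
                gts = []
                for si in range(n_samples):
                    if (config.missing_genotype_prob
                            and rng.random() < config.missing_genotype_prob):
                        gts.append(".|.")
                    else:
                        gts.append(f"{hap[2 * si]}|{hap[2 * si + 1]}")
                fh.write(f"{chrom}\t{pos + 1}\t.\t{'ACGT'[ref_code]}\t"
                         f"{'ACGT'[alt_code]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
                n_records += 1
    return n_records


# ---------------------------------------------------------------------------
# motifs, orthologs, GO assignments

def generate_pfms(config: SimulationConfig) -> list[dict]:
    """k PFMs of width 6..15 with a strong consensus."""
    rng = _rng(config, _S_MOTIFS)
    pfms = []
    for i in range(config.n_motifs):
        w = int(rng.integers(6, 16))
        consensus = rng.integers(0, 4, size=w)
        counts = rng.integers(0, 3, size=(4, w)).astype(float)
        counts[consensus, np.arange(w)] = 18.0
        pfms.append({
            "id": f"SM{i + 1:04d}.1",
            "name": f"SIMMOTIF{i + 1}",
            "counts": counts,
            "consensus": decode(consensus.astype(np.uint8)),
        })
    return pfms


def plant_motifs(
    config: SimulationConfig,
    reference: dict[str, np.ndarray],
    pfms: Sequence[dict],
) -> list[dict]:
    """Overwrite a fraction of planted elements with exact motif consensi.

    Mutates ``reference`` in place (must run before ``simulate_alignment``
    so the planted copy is shared by all species).  Elements shorter than
    every motif are skipped with a warning entry.
    """
    rng = np.random.default_rng([config.seed, _S_MOTIFS, 1])
    truth = []
    for chrom, s, e in config.planted_intervals():
        if rng.random() >= config.motif_plant_fraction:
            continue
        fitting = [p for p in pfms if len(p["consensus"]) <= e - s]
        if not fitting:
            truth.append({"chrom": chrom, "start": s, "end": e, "motif": None,
                          "note": "all motifs wider than element; skipped"})
            continue
        pfm = fitting[int(rng.integers(len(fitting)))]
        w = len(pfm["consensus"])
        offset = int(rng.integers(0, e - s - w + 1))
        codes = np.array([_CODE[b] for b in pfm["consensus"]], dtype=np.uint8)
        reference[chrom][s + offset:s + offset + w] = codes
        truth.append({"chrom": chrom, "start": s, "end": e,
                      "motif": pfm["id"], "offset": offset})
    return truth


def write_jaspar(pfms: Sequence[dict], path: str) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p['id']} {p['name']}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:6.0f}" for v in p["counts"][bi])
                fh.write(f"{base} [ {vals} ]\n")


def simulate_orthologs(
    config: SimulationConfig,
    genes: Sequence[SimulatedGene],
) -> tuple[dict[str, str], dict[str, str], list[SimulatedGene]]:
    """Ortholog tables for the reference species (A) and a comparator (B).

    Species B reuses the reference coordinates (its synthetic genome
    mirrors the reference) with its own gene ids.  A fraction of B genes
    get a mismatching orthogroup id, a fraction no entry at all.
    """
    rng = _rng(config, _S_ORTHO)
    table_a: dict[str, str] = {}
    table_b: dict[str, str] = {}
    genes_b: list[SimulatedGene] = []
    n = len(genes)
    for i, g in enumerate(genes):
        og = f"OG{i + 1:05d}"
        table_a[g.id] = og
        gb = SimulatedGene(
            id=f"B{g.id}", chrom=g.chrom, start=g.start, end=g.end,
            strand=g.strand, is_rna=g.is_rna, exons=list(g.exons),
            utr5=g.utr5, utr3=g.utr3,
        )
        genes_b.append(gb)
        u = rng.random()
        if u < config.ortholog_missing_fraction:
            continue
        if u < config.ortholog_missing_fraction + config.ortholog_mismatch_fraction:
            table_b[gb.id] = f"OGX{int(rng.integers(n, 2 * n)) + 1:05d}"
        else:
            table_b[gb.id] = og
    return table_a, table_b, genes_b


def write_ortholog_table(table: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\torthogroup_id\n")
        for gene, og in sorted(table.items()):
            fh.write(f"{gene}\t{og}\n")


def simulate_go_table(
    config: SimulationConfig,
    genes: Sequence[SimulatedGene],
    length_biased_fraction: float = 0.3,
    bias_power: float = 2.0,
) -> list[tuple[str, str, str]]:
    """(gene_id, go_id, namespace) rows; some terms preferentially hit long genes."""
    rng = _rng(config, _S_GO)
    lengths = np.array([g.length for g in genes], dtype=float)
    uniform_w = np.ones(len(genes)) / len(genes)
    biased_w = lengths ** bias_power
    biased_w /= biased_w.sum()
    namespaces = ["molecular_function", "biological_process", "cellular_component"]
    rows: list[tuple[str, str, str]] = []
    for t in range(config.n_go_terms):
        biased = rng.random() < length_biased_fraction
        size = int(rng.integers(max(2, len(genes) // 10), max(3, len(genes) // 3)))
        size = min(size, len(genes))
        w = biased_w if biased else uniform_w
        members = rng.choice(len(genes), size=size, replace=False, p=w)
        ns = namespaces[t % 3]
        for m in members:
            rows.append((genes[m].id, f"GO:{t + 1:07d}", ns))
    rows.sort()
    return rows


def write_go_table(rows: Sequence[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\tnamespace\n")
        for gene, go, ns in rows:
            fh.write(f"{gene}\t{go}\t{ns}\n")


# ---------------------------------------------------------------------------
# orchestrator

def simulate_all(config: SimulationConfig, outdir: str) -> dict[str, str]:
    """Generate every fixture type into ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "maf": os.path.join(outdir, "alignment.maf"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "gff_b": os.path.join(outdir, "genes_b.gff3"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "pfms": os.path.join(outdir, "motifs.jaspar"),
        "orthologs_a": os.path.join(outdir, "orthologs_a.tsv"),
        "orthologs_b": os.path.join(outdir, "orthologs_b.tsv"),
        "go": os.path.join(outdir, "go_terms.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    reference = simulate_reference(config)
    pfms = generate_pfms(config)
    motif_truth = plant_motifs(config, reference, pfms)
    blocks, _ = simulate_alignment(config, reference)
    genes = simulate_gene_models(config)
    table_a, table_b, genes_b = simulate_orthologs(config, genes)
    go_rows = simulate_go_table(config, genes)

    write_fasta(reference, paths["reference"])
    write_maf(blocks, paths["maf"])
    write_gff3(genes, paths["gff"])
    write_gff3(genes_b, paths["gff_b"])
    n_vcf = simulate_variants(config, reference, paths["vcf"])
    write_jaspar(pfms, paths["pfms"])
    write_ortholog_table(table_a, paths["orthologs_a"])
    write_ortholog_table(table_b, paths["orthologs_b"])
    write_go_table(go_rows, paths["go"])

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "planted_elements": [list(t) for t in config.planted_intervals()],
        "planted_motifs": motif_truth,
        "n_blocks": len(blocks),
        "n_vcf_records": n_vcf,
        "n_genes": len(genes),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return paths
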