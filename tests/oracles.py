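"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-column scans, per-base loops,
all-pairs comparisons, exhaustive enumeration, Monte-Carlo urns) and
shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

ACGT = "ACGT"


# ---------------------------------------------------------------------------
# discovery

def brute_force_runs(block, required, ref_species, min_len):
    """Maximal invariant runs by testing every start/length; ref + coords."""
    rows = {}
    for r in block.rows:
        rows[r.species] = r
    if any(sp not in rows for sp in required):
        return []
    ref = rows.get(ref_species)
    if ref is None:
        return []
    ncol = len(ref.text)

    def ok(col):
        chars = [rows[sp].text[col].upper() for sp in required]
        if any(c not in ACGT for c in chars):
            return False
        return len(set(chars)) == 1

    good = [ok(c) for c in range(ncol)]
    out = []
    for start in range(ncol):
        for end in range(start + min_len, ncol + 1):
            if all(good[c] for c in range(start, end)):
                maximal = ((start == 0 or not good[start - 1])
                           and (end == ncol or not good[end]))
                if maximal:
                    # reference coordinates, one base at a time
                    positions = []
                    seq = []
                    upto = 0
                    for c in range(ncol):
                        ch = ref.text[c]
                        if ch != "-":
                            if start <= c < end:
                                positions.append(ref.start + upto)
                                seq.append(ch.upper())
                            upto += 1
                    assert len(positions) == end - start
                    if ref.strand == "+":
                        s = positions[0]
                        out.append((ref.chromosome, s, s + end - start,
                                    "".join(seq)))
                    else:
                        s = ref.src_size - (positions[-1] + 1)
                        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                        rc = "".join(comp[c] for c in reversed(seq))
                        out.append((ref.chromosome, s, s + end - start, rc))
    out.sort()
    return out


def brute_force_mask(block, required, ref_species):
    """Eligible reference positions of one block, one column at a time."""
    rows = {r.species: r for r in block.rows}
    if any(sp not in rows for sp in required):
        return set()
    ref = rows.get(ref_species)
    if ref is None:
        return set()
    positions = set()
    upto = 0
    for c in range(len(ref.text)):
        chars = [rows[sp].text[c].upper() for sp in required]
        is_ref_base = ref.text[c] != "-"
        if all(ch in ACGT for ch in chars):
            assert is_ref_base
            if ref.strand == "+":
                positions.add(ref.start + upto)
            else:
                positions.add(ref.src_size - (ref.start + upto) - 1)
        if is_ref_base:
            upto += 1
    return positions


# ---------------------------------------------------------------------------
# annotation: per-base classifier straight from GFF text

def parse_gff_features(gff_path):
    """(seqid, type, start0, end0, parent_gene) tuples, no library."""
    feats = []
    id2gene = {}
    for line in open(gff_path):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        seqid, ftype, start, end, attrs = f[0], f[2], int(f[3]) - 1, int(f[4]), f[8]
        fid = parent = None
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                fid = kv[3:]
            elif kv.startswith("Parent="):
                parent = kv[7:]
        feats.append((seqid, ftype, start, end, fid, parent))
        if fid:
            id2gene[fid] = parent if parent else fid
    # resolve transcript -> gene
    def gene_of(fid):
        seen = set()
        while fid in id2gene and id2gene[fid] != fid and fid not in seen:
            seen.add(fid)
            fid = id2gene[fid]
        return fid
    return feats, gene_of


def brute_force_class(gff_path, chrom, pos):
    """Class of one base by scanning every feature line."""
    feats, _ = parse_gff_features(gff_path)
    in_exon = in_u5 = in_u3 = in_gene = in_rna = False
    for seqid, ftype, s, e, fid, parent in feats:
        if seqid != chrom or not (s <= pos < e):
            continue
        if ftype == "exon":
            in_exon = True
        elif ftype == "five_prime_UTR":
            in_u5 = True
        elif ftype == "three_prime_UTR":
            in_u3 = True
        elif ftype == "gene":
            in_gene = True
        elif ftype in ("ncRNA_gene",):
            in_rna = True
    if in_exon:
        return "exon"
    if in_u5:
        return "five_prime_utr"
    if in_u3:
        return "three_prime_utr"
    if in_gene:
        return "intron"
    if in_rna:
        return "rna_gene"
    return "intergenic"


# ---------------------------------------------------------------------------
# popgen: all-pairs brute force on a haplotype matrix

def parse_vcf_haplotypes(vcf_path):
    """chrom -> (positions list, haplotype allele matrix with -1 missing)."""
    out = {}
    for line in open(vcf_path):
        if line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        chrom, pos = f[0], int(f[1]) - 1
        if len(f[3]) != 1 or any(len(a) != 1 for a in f[4].split(",")):
            continue
        alleles = []
        for gt in f[9:]:
            for a in gt.replace("/", "|").split(":")[0].split("|"):
                alleles.append(-1 if a == "." else int(a))
        out.setdefault(chrom, ([], []))
        out[chrom][0].append(pos)
        out[chrom][1].append(alleles)
    return {c: (np.array(p), np.array(m)) for c, (p, m) in out.items()}


def brute_force_diversity(haps, chrom, start, end):
    """(S, pi, D) by explicit all-pairs comparison, constants from scratch."""
    if chrom not in haps:
        return 0, 0.0, None
    pos, mat = haps[chrom]
    sel = (pos >= start) & (pos < end)
    mat = mat[sel]
    S = 0
    pair_sum = 0.0
    n_hap = mat.shape[1] if mat.size else 0
    for row in mat:
        called = row[row >= 0]
        if called.size < 2:
            continue
        if len(set(called.tolist())) >= 2:
            S += 1
        # mean difference over all pairs of called haplotypes at this site
        diffs = pairs = 0
        for i in range(len(called)):
            for j in range(i + 1, len(called)):
                pairs += 1
                diffs += int(called[i] != called[j])
        if pairs:
            pair_sum += diffs / pairs
    pi = pair_sum / (end - start)
    if S == 0 or n_hap < 4:
        return S, pi, None
    n = n_hap  # oracle is used on complete-data VCFs only
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    D = (pair_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return S, pi, D


# ---------------------------------------------------------------------------
# motifs: exhaustive k-mer enumeration

def enumerate_score_distribution(int_weights, background):
    """Exact discretized null by summing over all 4^w k-mers."""
    w = int_weights.shape[1]
    iw = [[int(int_weights[b, j]) for b in range(4)] for j in range(w)]
    bg = [float(background[b]) for b in range(4)]
    masses = {}
    for kmer in itertools.product(range(4), repeat=w):
        score = 0
        prob = 1.0
        for j, b in enumerate(kmer):
            score += iw[j][b]
            prob *= bg[b]
        masses[score] = masses.get(score, 0.0) + prob
    return masses


def enumerate_tail(int_weights, background, threshold):
    masses = enumerate_score_distribution(int_weights, background)
    return sum(p for s, p in masses.items() if s >= threshold)


# ---------------------------------------------------------------------------
# Wallenius: sequential biased-urn Monte Carlo

def mc_wallenius_tail(k, n_draws_per_sim, n_term, n_total, odds, n_sims, rng):
    """P(X >= k) by simulating the biased urn n_sims times (vectorized)."""
    white = np.full(n_sims, n_term, dtype=np.int64)
    black = np.full(n_sims, n_total - n_term, dtype=np.int64)
    X = np.zeros(n_sims, dtype=np.int64)
    for _ in range(n_draws_per_sim):
        pw = odds * white / (odds * white + black)
        take_white = rng.random(n_sims) < pw
        X += take_white
        white -= take_white
        black -= ~take_white
    p = float((X >= k).mean())
    se = math.sqrt(max(p * (1 - p), 1e-12) / n_sims)
    return p, se
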