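import math

import numpy as np
import pytest

from ucescan.discovery import DiscoveryConfig, find_invariant_runs
from ucescan.mafio import read_maf
from ucescan.simulate import (
    SimulationConfig,
    SimulationError,
    decode,
    generate_pfms,
    harmonic_number,
    plant_motifs,
    random_planted_elements,
    simulate_all,
    simulate_alignment,
    simulate_gene_models,
    simulate_reference,
    simulate_variants,
)

from oracles import parse_vcf_haplotypes


def test_validation_rejects_overlapping_elements():
    cfg = SimulationConfig(seed=1, n_species=3, genome_length=1000,
                           planted_elements=[("chr1", 10, 30), ("chr1", 25, 30)])
    with pytest.raises(SimulationError, match="overlap"):
        cfg.validate()


def test_validation_rejects_element_outside_chromosome():
    cfg = SimulationConfig(seed=1, n_species=3, genome_length=100,
                           planted_elements=[("chr1", 90, 30)])
    with pytest.raises(SimulationError, match="outside"):
        cfg.validate()


def test_validation_rejects_bad_theta():
    cfg = SimulationConfig(seed=1, theta_neutral=-0.1)
    with pytest.raises(SimulationError, match="theta"):
        cfg.validate()


def test_zero_divergence_all_rows_identical_whole_blocks():
    cfg = SimulationConfig(seed=5, n_species=5, genome_length=5000,
                           divergence=0.0, gap_open_prob=0.0,
                           coverage_dropout_prob=0.0)
    blocks, ref = simulate_alignment(cfg)
    assert sum(b.n_columns for b in blocks) == 5000
    for b in blocks:
        assert len(b.rows) == 5
        texts = {r.text for r in b.rows}
        assert len(texts) == 1  # all rows identical everywhere
    # every maximal invariant run is a whole block
    recs = find_invariant_runs(blocks, DiscoveryConfig(reference_species="ref",
                                                       min_run_length=1))
    assert sorted((r.start, r.end) for r in recs) == sorted(
        (b.rows[0].start, b.rows[0].start + b.rows[0].size) for b in blocks)


def test_planted_element_recovered_exactly(tiny_config):
    cfg = tiny_config
    cfg.planted_elements = [("chr1", 2000, 50)]
    blocks, _ = simulate_alignment(cfg)
    recs = find_invariant_runs(blocks, DiscoveryConfig(reference_species="ref"))
    assert [(r.chromosome, r.start, r.end) for r in recs] == [("chr1", 2000, 2050)]


def test_mismatch_fraction_matches_binomial_oracle():
    d = 0.25
    cfg = SimulationConfig(seed=9, n_species=2, genome_length=20_000,
                           divergence=d, gap_open_prob=0.0,
                           coverage_dropout_prob=0.0)
    blocks, ref = simulate_alignment(cfg)
    p_expected = 1.0 - math.exp(-d)
    n = mism = 0
    for b in blocks:
        r0, r1 = b.rows[0].text, b.rows[1].text
        for a, c in zip(r0, r1):
            if c != "-":
                n += 1
                mism += a != c
    se = math.sqrt(p_expected * (1 - p_expected) / n)
    assert abs(mism / n - p_expected) < 3 * se


def test_alignment_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=21, n_species=5, genome_length=8000, n_genes=6)
    cfg.planted_elements = random_planted_elements(cfg, 5)
    p1 = simulate_all(cfg, str(tmp_path / "a"))
    p2 = simulate_all(cfg, str(tmp_path / "b"))
    for key in p1:
        assert open(p1[key]).read() == open(p2[key]).read(), key


def test_planted_elements_invariant_across_species(sim_bundle):
    cfg, paths = sim_bundle
    blocks = list(read_maf(paths["maf"]))
    for chrom, s, e in cfg.planted_intervals():
        for b in blocks:
            ref = b.row_for("ref")
            if (ref.chromosome == chrom and ref.plus_start() <= s
                    and e <= ref.plus_end()):
                cols = [i for i, ch in enumerate(ref.text) if ch != "-"]
                lo = cols[s - ref.plus_start()]
                hi = cols[e - ref.plus_start() - 1] + 1
                assert len(b.rows) == cfg.n_species  # no dropout
                segs = {r.text[lo:hi].upper() for r in b.rows}
                assert len(segs) == 1 and "-" not in segs.pop()
                break
        else:
            pytest.fail(f"planted element {chrom}:{s}-{e} not inside one block")


def test_maf_roundtrips_through_reader(sim_bundle):
    cfg, paths = sim_bundle
    blocks = list(read_maf(paths["maf"]))
    for b in blocks:
        b.validate()
    truth = __import__("json").load(open(paths["truth"]))
    assert len(blocks) == truth["n_blocks"]


# --- gene models -----------------------------------------------------------

def test_gene_density_zero_gives_empty_gff(tmp_path):
    cfg = SimulationConfig(seed=2, n_genes=0)
    genes = simulate_gene_models(cfg)
    assert genes == []


def test_gene_parts_tile_gene_exactly():
    cfg = SimulationConfig(seed=13, genome_length=200_000, n_genes=40,
                           rna_gene_fraction=0.2)
    genes = simulate_gene_models(cfg)
    assert any(g.is_rna for g in genes)
    for g in genes:
        if g.is_rna:
            continue
        parts = sorted([g.utr5, g.utr3] + g.exons)
        assert all(g.start <= s < e <= g.end for s, e in parts)
        # exon+UTR+implied introns tile the span: parts are disjoint, in-span
        for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
            assert e1 <= s2
        assert parts[0][0] == g.start and parts[-1][1] == g.end


def test_gene_overpacking_raises():
    cfg = SimulationConfig(seed=3, genome_length=3_000, n_genes=50)
    with pytest.raises(SimulationError, match="density"):
        simulate_gene_models(cfg)


def test_gene_base_totals_match_interval_union_oracle(tmp_path):
    from ucescan.annotation import build_feature_index
    from ucescan.simulate import write_gff3

    cfg = SimulationConfig(seed=17, genome_length=100_000, n_genes=20)
    genes = simulate_gene_models(cfg)
    path = str(tmp_path / "g.gff3")
    write_gff3(genes, path)
    idx = build_feature_index(path)
    totals = idx.class_base_totals()
    # per-base brute force from the generator's own structures
    expected = {"exon": 0, "five_prime_utr": 0, "three_prime_utr": 0,
                "intron": 0, "rna_gene": 0}
    for g in genes:
        if g.is_rna:
            expected["rna_gene"] += g.length
            continue
        covered = set()
        for s, e in g.exons:
            expected["exon"] += e - s
            covered.update(range(s, e))
        expected["five_prime_utr"] += g.utr5[1] - g.utr5[0]
        covered.update(range(*g.utr5))
        expected["three_prime_utr"] += g.utr3[1] - g.utr3[0]
        covered.update(range(*g.utr3))
        expected["intron"] += g.length - len(covered)
    assert totals == expected


# --- variants --------------------------------------------------------------

def test_zero_constrained_theta_means_no_snps_in_elements(sim_bundle, tmp_path):
    cfg, paths = sim_bundle
    haps = parse_vcf_haplotypes(paths["vcf"])
    for chrom, s, e in cfg.planted_intervals():
        if chrom in haps:
            pos, _ = haps[chrom]
            assert not ((pos >= s) & (pos < e)).any()


def test_watterson_expected_segregating_sites(tmp_path):
    theta, n_hap, L = 0.02, 10, 50_000
    cfg = SimulationConfig(seed=31, n_species=2, genome_length=L,
                           theta_neutral=theta, n_haplotypes=n_hap)
    ref = simulate_reference(cfg)
    path = str(tmp_path / "v.vcf")
    n = simulate_variants(cfg, ref, path)
    lam = theta * L * harmonic_number(n_hap)
    assert abs(n - lam) < 3 * math.sqrt(lam)


def test_singleton_fraction_matches_sfs_oracle(tmp_path):
    theta, n_hap, L = 0.02, 20, 50_000
    cfg = SimulationConfig(seed=37, n_species=2, genome_length=L,
                           theta_neutral=theta, n_haplotypes=n_hap)
    ref = simulate_reference(cfg)
    path = str(tmp_path / "v.vcf")
    simulate_variants(cfg, ref, path)
    haps = parse_vcf_haplotypes(path)
    pos, mat = haps["chr1"]
    derived = (mat == 1).sum(axis=1)
    frac = float((derived == 1).mean())
    expected = 1.0 / harmonic_number(n_hap)
    se = math.sqrt(expected * (1 - expected) / len(pos))
    assert abs(frac - expected) < 3 * se


def test_variants_sorted_and_parse(sim_bundle):
    cfg, paths = sim_bundle
    haps = parse_vcf_haplotypes(paths["vcf"])
    for chrom, (pos, mat) in haps.items():
        assert (np.diff(pos) > 0).all()
        assert mat.shape[1] == cfg.n_haplotypes


# --- motifs / orthologs ----------------------------------------------------

def test_plant_fraction_one_marks_every_element():
    cfg = SimulationConfig(seed=41, genome_length=20_000, motif_plant_fraction=1.0)
    cfg.planted_elements = random_planted_elements(cfg, 10, (20, 60))
    ref = simulate_reference(cfg)
    pfms = generate_pfms(cfg)
    truth = plant_motifs(cfg, ref, pfms)
    planted = [t for t in truth if t.get("motif")]
    assert len(planted) == 10
    for t in planted:
        pfm = next(p for p in pfms if p["id"] == t["motif"])
        region = decode(ref[t["chrom"]][t["start"] + t["offset"]:
                                        t["start"] + t["offset"] + len(pfm["consensus"])])
        assert region == pfm["consensus"]


def test_motif_wider_than_element_skipped():
    cfg = SimulationConfig(seed=43, genome_length=5_000, motif_plant_fraction=1.0,
                           planted_elements=[("chr1", 100, 4)])
    ref = simulate_reference(cfg)
    pfms = generate_pfms(cfg)  # widths 6..15 > 4
    truth = plant_motifs(cfg, ref, pfms)
    assert truth and truth[0]["motif"] is None


def test_pfm_widths_in_range():
    cfg = SimulationConfig(seed=47, n_motifs=20)
    for p in generate_pfms(cfg):
        assert 6 <= len(p["consensus"]) <= 15
        assert p["counts"].shape == (4, len(p["consensus"]))
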