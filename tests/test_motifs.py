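import math

import numpy as np
import pytest

from ucescan.discovery import UCERecord
from ucescan.motifs import (
    PFM,
    cas9_targets,
    estimate_background,
    has_cas9_site,
    pfm_to_pwm,
    read_jaspar,
    scan,
    score_pvalue_table,
)
from ucescan.simulate import SimulationConfig, generate_pfms, write_jaspar

from oracles import enumerate_score_distribution


def test_pfm_validation():
    with pytest.raises(ValueError, match="positive"):
        PFM("x", "x", np.zeros((4, 3)))
    with pytest.raises(ValueError, match="negative"):
        PFM("x", "x", -np.ones((4, 3)))


def test_uniform_counts_uniform_background_zero_weights():
    pfm = PFM("m", "m", np.full((4, 5), 2.0))
    pwm = pfm_to_pwm(pfm, pseudocount=0.0)
    assert np.allclose(pwm, 0.0)


def test_single_column_arithmetic_oracle():
    pfm = PFM("m", "m", np.array([[10.0], [0.0], [0.0], [0.0]]))
    pwm = pfm_to_pwm(pfm, pseudocount=0.1)
    expected_a = math.log2(((10 + 0.1 * 0.25) / 10.1) / 0.25)
    assert pwm[0, 0] == pytest.approx(expected_a, abs=1e-12)
    expected_c = math.log2(((0 + 0.1 * 0.25) / 10.1) / 0.25)
    assert pwm[1, 0] == pytest.approx(expected_c, abs=1e-12)


def test_weights_monotone_in_counts():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 30, size=(4, 6)).astype(float) + 1
    pwm = pfm_to_pwm(PFM("m", "m", counts))
    for j in range(6):
        order_counts = np.argsort(counts[:, j])
        assert (np.diff(pwm[order_counts, j]) >= -1e-12).all()


def test_zero_background_entry_raises():
    pfm = PFM("m", "m", np.ones((4, 3)))
    with pytest.raises(ValueError):
        pfm_to_pwm(pfm, background=np.array([0.5, 0.5, 0.0, 0.0]))


# --- exact p-value table ---------------------------------------------------

def test_w1_uniform_background_quarter_masses():
    pwm = pfm_to_pwm(PFM("m", "m", np.array([[8.], [4.], [2.], [1.]])))
    table = score_pvalue_table(pwm)
    # 4 distinct scores, each with mass 0.25
    nz = table.pmf[table.pmf > 0]
    assert nz.size == 4
    assert np.allclose(nz, 0.25)
    assert table.pmf.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("w", [2, 4, 6, 8])
def test_table_equals_exhaustive_enumeration(w):
    rng = np.random.default_rng(w)
    counts = rng.integers(0, 20, size=(4, w)).astype(float) + 0.5
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    pwm = pfm_to_pwm(PFM("m", "m", counts), background=bg)
    table = score_pvalue_table(pwm, background=bg)
    masses = enumerate_score_distribution(table.int_weights, bg)
    for score, prob in masses.items():
        i = score - table.min_score
        assert table.pmf[i] == pytest.approx(prob, abs=1e-12)
        tail = sum(p for s, p in masses.items() if s >= score)
        assert table.tail[i] == pytest.approx(tail, abs=1e-12)
    # entries not in the enumeration must be zero
    hit = {s - table.min_score for s in masses}
    for i in range(table.pmf.size):
        if i not in hit:
            assert table.pmf[i] == 0.0


def test_max_score_tail_equals_consensus_probability():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 25, size=(4, 7)).astype(float)
    bg = np.array([0.25, 0.3, 0.2, 0.25])
    pwm = pfm_to_pwm(PFM("m", "m", counts), background=bg)
    table = score_pvalue_table(pwm, background=bg)
    best = table.int_weights.max(axis=0)
    # probability of drawing the arg-max base at every column
    prob = 1.0
    for j in range(7):
        winners = np.flatnonzero(table.int_weights[:, j] == best[j])
        prob *= bg[winners].sum()
    assert table.pvalue(int(best.sum())) == pytest.approx(prob, rel=1e-10)


def test_tail_monotone_and_total_mass():
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 15, size=(4, 10)).astype(float) + 0.25
    pwm = pfm_to_pwm(PFM("m", "m", counts))
    table = score_pvalue_table(pwm)
    assert (np.diff(table.tail) <= 1e-15).all()
    assert table.pmf.sum() == pytest.approx(1.0, abs=1e-12)


def test_granularity_guard():
    pwm = np.tile(np.array([[5.0], [-5.0], [0.0], [0.0]]), (1, 30))
    with pytest.raises(ValueError, match="granularity"):
        score_pvalue_table(pwm, granularity=1e-7)


# --- scanning --------------------------------------------------------------

def _simple_pfm():
    counts = np.zeros((4, 8))
    consensus = [0, 2, 0, 3, 1, 2, 3, 0]  # AGATCGTA
    for j, b in enumerate(consensus):
        counts[b, j] = 20
    return PFM("M1", "M1", counts + 0.5), "AGATCGTA"


def test_planted_consensus_found_at_q1():
    pfm, consensus = _simple_pfm()
    rng = np.random.default_rng(2)
    seqs = {}
    for i in range(10):
        bgseq = "".join(rng.choice(list("ACGT"), size=40))
        seqs[f"s{i}"] = bgseq[:16] + consensus + bgseq[16:]
    hits, has_hit, n_tests = scan(seqs, [pfm], q_threshold=1.000001)
    assert all(has_hit.values())
    mine = hits[(hits.sequence_id == "s0") & (hits.strand == "+")]
    assert 16 in set(mine.start)


def test_strand_symmetry():
    pfm, consensus = _simple_pfm()
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    bg = np.full(4, 0.25)  # strand-symmetric background
    h1, _, _ = scan({"a": seq}, [pfm], q_threshold=1.1, background=bg)
    h2, _, _ = scan({"a": rc}, [pfm], q_threshold=1.1, background=bg)
    k1 = sorted(zip(h1.start, h1.strand, h1.score.round(6), h1.p_value))
    flipped = [(len(seq) - s - pfm.width, "+" if st == "-" else "-", sc, p)
               for s, st, sc, p in zip(h2.start, h2.strand,
                                       h2.score.round(6), h2.p_value)]
    assert k1 == sorted(flipped)


def test_sequence_shorter_than_motif_skipped():
    pfm, _ = _simple_pfm()
    hits, has_hit, n_tests = scan({"tiny": "ACG"}, [pfm], q_threshold=1.0)
    assert n_tests == 0 and has_hit == {"tiny": False}


def test_null_scan_pvalue_calibration():
    # information-rich random PFM: the null score spectrum is dense, so
    # attainable p-values approximate the continuous uniform closely
    rng = np.random.default_rng(11)
    pfm = PFM("R1", "R1", rng.integers(1, 40, size=(4, 10)).astype(float))
    # independent sequences of exactly motif length: one + and one - test each
    seqs = {f"r{i}": "".join(rng.choice(list("ACGT"), size=10))
            for i in range(3000)}
    bg = np.full(4, 0.25)
    # q_threshold > 1 retains every test, exposing all raw p-values
    hits, _, n_tests = scan(seqs, [pfm], q_threshold=1.1, background=bg)
    for alpha in (0.05, 0.2):
        frac = float((hits.p_value < alpha).mean())
        se = math.sqrt(alpha * (1 - alpha) / len(seqs))
        assert abs(frac - alpha) < 3 * se


def test_bh_q_monotone_in_p():
    pfm, consensus = _simple_pfm()
    rng = np.random.default_rng(6)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=30)) for i in range(20)}
    hits, _, _ = scan(seqs, [pfm], q_threshold=1.1)
    df = hits.sort_values("p_value")
    assert (np.diff(df.q_value.to_numpy()) >= -1e-12).all()
    assert (df.q_value.to_numpy() >= df.p_value.to_numpy() - 1e-12).all()


def test_jaspar_roundtrip(tmp_path):
    cfg = SimulationConfig(seed=19, n_motifs=4)
    pfms = generate_pfms(cfg)
    path = str(tmp_path / "m.jaspar")
    write_jaspar(pfms, path)
    loaded = read_jaspar(path)
    assert [p.id for p in loaded] == [p["id"] for p in pfms]
    for a, b in zip(loaded, pfms):
        assert np.allclose(a.counts, b["counts"])


def test_estimate_background():
    bg = estimate_background({"a": "AAAA", "b": "CCCC"})
    assert np.allclose(bg, np.array([5, 5, 1, 1]) / 12)  # add-one smoothed
    assert (bg > 0).all()
    assert np.allclose(estimate_background({}), 0.25)


# --- Cas9 ------------------------------------------------------------------

def test_cas9_18bp_has_no_room():
    assert has_cas9_site("A" * 18) is False


def test_cas9_21bp_ending_agg():
    seq = "ACGTACGTACGTACGTAC" + "AGG"
    assert len(seq) == 21
    assert has_cas9_site(seq) is True


def test_cas9_ccn_prefix():
    seq = "CCT" + "ACGTACGTACGTACGTAA"
    assert len(seq) == 21
    assert has_cas9_site(seq) is True


def test_cas9_no_pam_false():
    assert has_cas9_site("ATATATATATATATATATATATATA") is False


def test_cas9_summary_separates_repeats():
    recs = [
        UCERecord("c", 0, 21, "ACGTACGTACGTACGTACAGG", id="a"),
        UCERecord("c", 30, 51, "ACGTACGTACGTACGTACAGG", id="b"),
        UCERecord("c", 60, 78, "ATATATATATATATATAT", id="d"),
    ]
    recs[0].is_repeat = False
    recs[1].is_repeat = True
    recs[2].is_repeat = False
    flags, summary = cas9_targets(recs)
    assert flags == {"a": True, "b": True, "d": False}
    assert summary["n_with_target"] == 2
    assert summary["n_repeat_flagged_with_target"] == 1
    assert summary["n_unique_with_target"] == 1
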