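"""Nearest-neighbor thermodynamics against an independently coded table-sum
oracle, dimer/hairpin annealing against exhaustive structure enumeration."""

import math

import numpy as np
import pytest

from bacseq.genome_io import reverse_complement
from bacseq.thermo import (
    default_table,
    duplex_thermo,
    load_nn_table,
    oligo_dimers,
    oligo_hairpin,
    scan_hairpins,
)

from conftest import random_dna

# Independent oracle: unified DNA nearest-neighbor parameters transcribed
# directly from the published set (dH kcal/mol, dS cal/(mol*K)), summed
# spreadsheet-style without going through the package's loader or scorer.
ORACLE_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
ORACLE_INIT_GC = (0.1, -2.8)
ORACLE_INIT_AT = (2.3, 4.1)
ORACLE_SYM_DS = -1.4
R = 1.9872


def oracle_thermo(seq, conc):
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = ORACLE_NN[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = ORACLE_INIT_GC if end in "GC" else ORACLE_INIT_AT
        dh += h
        ds += s
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        ds += ORACLE_SYM_DS
    x = 1.0 if selfcomp else 4.0
    tm = 1000.0 * dh / (ds + R * math.log(conc / x)) - 273.15
    return dh, ds, tm


def test_dg37_identity_property(rng):
    for _ in range(20):
        seq = random_dna(rng, int(rng.integers(8, 30)))
        r = duplex_thermo(seq)
        assert np.isclose(r.dG37, r.dH - 310.15 * r.dS / 1000.0, atol=1e-9)


def test_tm_matches_table_sum_oracle():
    r = duplex_thermo("ACGTACGTACGTACGT", oligo_conc=0.25e-6)
    dh, ds, tm = oracle_thermo("ACGTACGTACGTACGT", 0.25e-6)
    assert abs(r.dH - dh) < 1e-9 and abs(r.dS - ds) < 1e-9
    assert abs(r.tm - tm) < 1e-6


def test_hundred_random_oligos_match_oracle(rng):
    for _ in range(100):
        seq = random_dna(rng, int(rng.integers(8, 35)))
        conc = float(rng.uniform(0.05e-6, 2e-6))
        r = duplex_thermo(seq, oligo_conc=conc)
        dh, ds, tm = oracle_thermo(seq, conc)
        assert abs(r.dH - dh) < 0.01 and abs(r.dG37 - (dh - 310.15 * ds / 1000)) < 0.01
        assert abs(r.tm - tm) < 0.1


def test_gc_more_stable_than_at():
    gc = duplex_thermo("GCGCGCGCGC")
    at = duplex_thermo("ATATATATAT")
    assert gc.tm > at.tm


def test_self_complementary_symmetry_correction():
    # GAATTC is its own reverse complement: symmetry term and x = 1 apply
    r_sc = duplex_thermo("GAATTC")
    dh, ds, tm = oracle_thermo("GAATTC", 0.25e-6)
    assert abs(r_sc.dS - ds) < 1e-9
    assert abs(r_sc.tm - tm) < 1e-6


def test_non_acgt_rejected():
    with pytest.raises(ValueError):
        duplex_thermo("ACGX")


def test_appending_gc_pair_never_raises_dg():
    seq = "ATGCATGC"
    for _ in range(5):
        base = duplex_thermo(seq).dG37
        seq = seq + "G"
        assert duplex_thermo(seq).dG37 <= base


# --- dimers --------------------------------------------------------------------


def test_perfect_complement_dimer_equals_duplex():
    a = "ACGTTGCAGGTT"  # not self-complementary
    best = oligo_dimers(a, reverse_complement(a), top_n=1)[0]
    assert len(best.paired) == len(a)
    assert np.isclose(best.result.dG37, duplex_thermo(a).dG37)


def test_poly_a_no_dimer():
    assert oligo_dimers("AAAA", "AAAA") == []


def test_partial_3prime_overlap_best_offset():
    # construct a and b sharing a designed 6 bp 3'-complementary overlap
    rng = np.random.default_rng(3)
    a = random_dna(rng, 14) + "GGCAGC"
    b = random_dna(rng, 14) + reverse_complement("GGCAGC")
    structures = oligo_dimers(a, b, top_n=50, min_run=2)
    # exhaustive offset oracle: longest complementary run must be the overlap
    best = structures[0]
    a_idx = [i for i, _ in best.paired]
    assert set(range(14, 20)) <= set(a_idx)


# --- hairpins ------------------------------------------------------------------


def test_designed_hairpin_found():
    (best, *_rest) = oligo_hairpin("GGGGAAAACCCC")
    assert best.result.dG37 < 0
    assert best.paired == [(0, 11), (1, 10), (2, 9), (3, 8)]
    assert best.offset == 4  # loop length


def test_poly_a_no_hairpin():
    assert oligo_hairpin("A" * 12) == []


def pairs_ok(seq, i, j):
    return {seq[i], seq[j]} in ({"A", "T"}, {"G", "C"})


def brute_force_best_hairpin(seq, table):
    """Exhaustive stem-position enumeration with independent dG arithmetic."""
    best = None
    for i in range(len(seq)):
        for s in range(2, len(seq)):
            for loop in range(3, len(seq)):
                j0 = i + s + loop
                if j0 + s > len(seq):
                    break
                if all(pairs_ok(seq, i + t, j0 + s - 1 - t) for t in range(s)):
                    dh = sum(ORACLE_NN[seq[i + t : i + t + 2]][0] for t in range(s - 1))
                    ds = sum(ORACLE_NN[seq[i + t : i + t + 2]][1] for t in range(s - 1))
                    ds += -table.loop_penalty(loop) * 1000.0 / 310.15
                    dg = dh - 310.15 * ds / 1000.0
                    if best is None or dg < best[0]:
                        best = (dg, i, s, loop)
    return best


def test_random_20mers_match_bruteforce(rng):
    table = default_table("DNA")
    found = 0
    for _ in range(30):
        seq = random_dna(rng, 20)
        structures = oligo_hairpin(seq, min_stem=2)
        oracle = brute_force_best_hairpin(seq, table)
        if oracle is None:
            assert structures == []
            continue
        found += 1
        assert np.isclose(structures[0].result.dG37, oracle[0], atol=1e-9)
    assert found > 5  # the check must actually exercise folds


def test_scan_finds_planted_terminator_hairpin(rng):
    bg = random_dna(rng, 400)
    stem = "GCCGCGGGCC"
    genome = bg[:200] + stem + "TTTT" + reverse_complement(stem) + bg[200:]
    cands = scan_hairpins(genome, window=60, min_stem=4, max_loop=10, dg_threshold=-8.0)
    assert any(c.pos == 200 and c.stem_len == 10 and c.loop_len == 4 for c in cands)


def test_poly_a_genome_no_hairpins():
    assert scan_hairpins("A" * 500, window=40, dg_threshold=-1.0) == []


def test_scan_matches_windowed_bruteforce(rng):
    seq = random_dna(rng, 1000)
    rna_table = load_nn_table("RNA")
    got = scan_hairpins(seq, window=30, min_stem=4, max_loop=8, dg_threshold=-4.0,
                        both_strands=False)
    # independent enumeration on the forward strand
    rna = seq.replace("T", "U")
    def rpair(x, y):
        return {x, y} in ({"A", "U"}, {"G", "C"})
    brute = []
    for i in range(len(rna)):
        for s in range(4, 14):
            for loop in range(3, 9):
                j0 = i + s + loop
                span = 2 * s + loop
                if span > 30 or j0 + s > len(rna):
                    continue
                if all(rpair(rna[i + t], rna[j0 + s - 1 - t]) for t in range(s)):
                    dh = sum(rna_table.dH[rna[i + t : i + t + 2]] for t in range(s - 1))
                    ds = sum(rna_table.dS[rna[i + t : i + t + 2]] for t in range(s - 1))
                    ds += -rna_table.loop_penalty(loop) * 1000 / 310.15
                    dg = dh - 310.15 * ds / 1000
                    if dg <= -4.0:
                        brute.append((i, s, loop, dg))
    # every reported candidate must be in the brute-force set, and the
    # brute-force optimum must be reported (dedup keeps the most stable)
    brute_set = {(b[0], b[1], b[2]) for b in brute}
    for c in got:
        assert (c.pos, c.stem_len, c.loop_len) in brute_set
    if brute:
        best = min(brute, key=lambda b: b[3])
        assert any(np.isclose(c.dG, best[3]) for c in got)
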