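"""Composition profiles, codon usage, ORFs, k-word search, repeats and
restriction mapping, each checked against an independent brute-force oracle
where the computation is non-trivial."""

import numpy as np
import pytest

from bacseq.genome_io import Annotation, Feature, GenomeSequence, reverse_complement
from bacseq.seq_tools import (
    codon_usage,
    find_orfs,
    find_repeats,
    gc_profile,
    kword_search,
    restriction_map,
)

from conftest import random_dna

# --- GC profiles ----------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,kind,expected",
    [("ATAT", "content", 0.0), ("GGGG", "skew", 1.0), ("GCGC", "skew", 0.0), ("GCGC", "content", 1.0)],
)
def test_gc_single_window(seq, kind, expected):
    prof = gc_profile(seq, window=4, kind=kind)
    assert prof.values[0] == expected


def test_gc_plus_at_is_one(rng):
    seq = random_dna(rng, 500)
    gc = gc_profile(seq, window=50, step=7).values
    at = np.array(
        [
            (seq[s : s + 50].count("A") + seq[s : s + 50].count("T")) / 50
            for s in range(0, 451, 7)
        ]
    )
    assert np.allclose(gc + at, 1.0)


def test_gc_window_larger_than_sequence_warns():
    with pytest.warns(UserWarning):
        prof = gc_profile("ACGT", window=10)
    assert len(prof.values) == 1


def test_gc_skew_zero_without_gc():
    assert gc_profile("ATATAT", window=6, kind="skew").values[0] == 0.0


# --- codon usage -----------------------------------------------------------------


def test_codon_usage_single_met():
    g = GenomeSequence("g", "ATGATGTAA")
    ann = Annotation("g", [Feature(id="c", ftype="CDS", start=0, end=9)])
    df = codon_usage(ann, g)
    met = df[df.codon == "ATG"]
    assert met.fraction.iloc[0] == 1.0
    assert df[df.codon == "TAA"].aa.iloc[0] == "*"


def test_codon_usage_family_fractions():
    # Lys family: AAA x3, AAG x1 -> 0.75/0.25
    g = GenomeSequence("g", "ATG" + "AAA" * 3 + "AAG" + "TAA")
    ann = Annotation("g", [Feature(id="c", ftype="CDS", start=0, end=len(g.seq))])
    df = codon_usage(ann, g).set_index("codon")
    assert df.loc["AAA"].fraction == 0.75
    assert df.loc["AAG"].fraction == 0.25


def test_codon_usage_fractions_sum_per_family(rng):
    seq = "ATG" + random_dna(rng, 3 * 200) + "TAA"
    g = GenomeSequence("g", seq)
    ann = Annotation("g", [Feature(id="c", ftype="CDS", start=0, end=len(seq))])
    df = codon_usage(ann, g)
    sums = df.groupby("aa").fraction.sum()
    assert np.allclose(sums, 1.0)


def test_codon_usage_requires_cds():
    g = GenomeSequence("g", "ATGAAATAA")
    with pytest.raises(ValueError, match="CDS"):
        codon_usage(Annotation("g"), g)


# --- ORFs -------------------------------------------------------------------------


def test_single_orf_plus_strand():
    (f,) = find_orfs("ATGAAATAG", min_len=9)
    assert (f.start, f.end, f.strand) == (0, 9, "+")


def test_single_orf_minus_strand():
    (f,) = find_orfs(reverse_complement("ATGAAATAG"), min_len=9)
    assert (f.start, f.end, f.strand) == (0, 9, "-")


def brute_force_orfs(seq, min_len, starts=("ATG", "GTG", "TTG")):
    """Independent six-frame scanner (first start after each stop, per frame)."""
    stops = {"TAA", "TAG", "TGA"}
    out = set()
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            first_start = None
            for i in range(frame, len(s) - 2, 3):
                cod = s[i : i + 3]
                if cod in stops:
                    if first_start is not None and i + 3 - first_start >= min_len:
                        a, b = first_start, i + 3
                        if strand == "-":
                            a, b = len(s) - b, len(s) - a
                        out.add((a, b, strand))
                    first_start = None
                elif first_start is None and cod in starts:
                    first_start = i
    return out


def test_orfs_match_bruteforce_on_random_sequence(rng):
    seq = random_dna(rng, 10_000)
    got = {(f.start, f.end, f.strand) for f in find_orfs(seq, min_len=60)}
    assert got == brute_force_orfs(seq, 60)


def test_circular_orf_across_origin():
    # ORF: ATG AAA CCC TAG wrapping the origin
    orf = "ATGAAACCCTAG"
    seq = orf[6:] + "CCTTCCTTCCTT" + orf[:6]
    feats = find_orfs(GenomeSequence("g", seq, circular=True), min_len=12)
    wrapped = [f for f in feats if f.parts]
    assert wrapped
    f = wrapped[0]
    assert len(f) == 12
    assert f.start == 18


# --- k-word search -----------------------------------------------------------------


def nw_global(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Independent full-matrix Needleman-Wunsch score."""
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    M[:, 0] = gap * np.arange(n + 1)
    M[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = M[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            M[i, j] = max(d, M[i - 1, j] + gap, M[i, j - 1] + gap)
    return M[n, m]


def test_identity_search(rng):
    s = random_dna(rng, 120)
    (h,) = kword_search(s, s, k=11)
    assert h.identity == 1.0
    assert (h.q_start, h.q_end, h.s_start, h.s_end) == (0, 120, 0, 120)
    assert h.score == nw_global(s, s)


def test_single_substitution(rng):
    q = random_dna(rng, 100)
    s = list(q)
    s[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[50]]
    s = "".join(s)
    (h,) = kword_search(q, s, k=11, min_identity=0.9)
    assert abs(h.identity - 0.99) < 1e-9
    assert h.score == nw_global(q, s)


def test_no_shared_kword_empty():
    assert kword_search("A" * 40, "C" * 200, k=11) == []


def test_reverse_strand_hit(rng):
    q = random_dna(rng, 60)
    subject = random_dna(rng, 100) + reverse_complement(q) + random_dna(rng, 100)
    hits = kword_search(q, subject, k=11, both_strands=True)
    minus = [h for h in hits if h.strand == "-"]
    assert minus and minus[0].s_start == 100 and minus[0].s_end == 160
    assert minus[0].identity == 1.0


# --- repeats ------------------------------------------------------------------------


def test_inverted_repeat_trivial():
    (h,) = find_repeats("AAAATTTT", 4, 0, "inverted")
    assert (h.pos1, h.pos2, h.kind) == (0, 4, "inverted")


def test_direct_repeat_trivial():
    hits = find_repeats("ACGTACGT", 4, 0, "direct")
    assert any((h.pos1, h.pos2) == (0, 4) for h in hits)


def brute_force_repeats(seq, N, K_max):
    out = set()
    for p in range(len(seq)):
        for K in range(K_max + 1):
            q = p + N + K
            if q + N > len(seq):
                break
            u1, u2 = seq[p : p + N], seq[q : q + N]
            if u1 == u2:
                out.add((p, q, N, K, "direct"))
            if u2 == reverse_complement(u1):
                out.add((p, q, N, K, "inverted"))
    return out


def test_repeats_match_quadratic_oracle(rng):
    seq = random_dna(rng, 2000)
    for N in (4, 6, 8):
        got = {(h.pos1, h.pos2, h.unit_len, h.spacer, h.kind) for h in find_repeats(seq, N, 20)}
        assert got == brute_force_repeats(seq, N, 20)


# --- restriction mapping --------------------------------------------------------------


def test_ecori_single_site():
    hits = restriction_map("GAATTC", {"EcoRI": "GAATTC"})
    assert hits == [("EcoRI", 0, "+")]  # palindrome reported once


def test_no_sites():
    assert restriction_map("AAAA", {"EcoRI": "GAATTC"}) == []


def test_degenerate_site_matches_both():
    hits = restriction_map("GGACCTTTGGTCC", {"AvaII": "GGWCC"})
    positions = {(p, s) for _, p, s in hits}
    assert (0, "+") in positions and (8, "+") in positions


def test_non_palindromic_both_strands():
    # HgaI-like non-palindromic site GACGC; revcomp GCGTC
    hits = restriction_map("GACGCAAAGCGTC", {"HgaI": "GACGC"})
    assert ("HgaI", 0, "+") in hits and ("HgaI", 8, "-") in hits


def test_circular_site_across_origin():
    g = GenomeSequence("g", "TTCAAAAAAGAA", circular=True)
    hits = restriction_map(g, {"EcoRI": "GAATTC"})
    assert ("EcoRI", 9, "+") in hits


def test_invalid_iupac_symbol():
    with pytest.raises(ValueError, match="IUPAC"):
        restriction_map("ACGT", {"bad": "GAXTC"})
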