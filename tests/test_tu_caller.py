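"""Step detection, significance-tested interval merging and TU/TSS calling."""

import numpy as np
import pytest

from bacseq.coverage import CoverageTrack
from bacseq.tu_caller import (
    call_transcription_units,
    call_tss,
    call_tus,
    detect_steps,
    merge_intervals,
)


def track(values, mode="full_read", strand="both"):
    return CoverageTrack("g", strand, mode, np.asarray(values, dtype=float))


# --- detect_steps -------------------------------------------------------------


def test_constant_track_no_steps():
    assert detect_steps(track(np.full(100, 8.0))) == []


def test_perfect_step_single_changepoint():
    c = np.zeros(60)
    c[30:] = 100.0
    steps = detect_steps(track(c), smooth_window=1, min_magnitude=5)
    assert len(steps) == 1
    assert steps[0].pos == 30
    assert steps[0].direction == "up"
    assert steps[0].magnitude == 100.0


def test_two_step_staircase_matches_boundary_scan():
    c = np.zeros(50)
    c[20:] = 50.0
    c[35:] = 100.0
    steps = detect_steps(track(c), smooth_window=1, min_magnitude=5)
    # independent oracle: scan every boundary of the raw vector for jumps
    oracle = [i for i in range(1, 50) if abs(c[i] - c[i - 1]) >= 5]
    assert [s.pos for s in steps] == oracle == [20, 35]
    assert all(s.direction == "up" for s in steps)


def test_down_step_direction():
    c = np.full(40, 80.0)
    c[25:] = 2.0
    (s,) = detect_steps(track(c), smooth_window=1)
    assert s.direction == "down" and s.pos == 25


def test_invalid_window_errors():
    with pytest.raises(ValueError):
        detect_steps(track(np.ones(10)), smooth_window=0)


# --- merge_intervals ----------------------------------------------------------


def reachable_fixed_points(values, boundaries, sd_threshold, sd_floor=1.0):
    """Oracle: exhaustively explore every order of removing insignificant
    boundaries; return all boundary sets where no further removal is possible.

    Feasible only for a handful of candidate boundaries.
    """
    values = np.asarray(values, dtype=float)
    L = len(values)

    def significant(i, j, k):
        a = values[i:j]
        b = values[j:k]
        return abs(a.mean() - b.mean()) > sd_threshold * max(a.std(), b.std(), sd_floor)

    results = set()

    def explore(keep):
        pts = [0, *keep, L]
        removable = [
            keep[i] for i in range(len(keep)) if not significant(pts[i], pts[i + 1], pts[i + 2])
        ]
        if not removable:
            results.add(tuple(keep))
            return
        for b in removable:
            explore(tuple(x for x in keep if x != b))

    explore(tuple(sorted(boundaries)))
    return [list(r) for r in results]


def test_identical_intervals_merge_to_one():
    c = np.full(100, 20.0)
    from bacseq.tu_caller import ChangePoint

    steps = [ChangePoint(pos=50, direction="up", magnitude=1.0)]
    ivs = merge_intervals(track(c), steps)
    assert len(ivs) == 1
    assert (ivs[0].start, ivs[0].end) == (0, 100)


def test_very_different_intervals_stay_separate():
    c = np.concatenate([np.full(50, 10.0), np.full(50, 1000.0)])
    steps = detect_steps(track(c), smooth_window=1)
    ivs = merge_intervals(track(c), steps, sd_threshold=5.0)
    assert len(ivs) == 2
    assert ivs[0].end == 50


def test_noisy_three_levels_recovered(rng):
    # 5 noisy segments but only 3 true levels: flanking boundaries must go
    means = [5, 100, 100, 100, 5]
    bounds = [40, 80, 120, 160]
    c = np.concatenate([rng.normal(m, 1.0, 40).clip(0) for m in means])
    from bacseq.tu_caller import ChangePoint

    steps = [ChangePoint(pos=b, direction="up", magnitude=1.0) for b in bounds]
    ivs = merge_intervals(track(c), steps, sd_threshold=2.0)
    got = sorted(iv.start for iv in ivs[1:])
    oracle = reachable_fixed_points(c, bounds, 2.0)
    assert got in oracle
    assert got == [40, 160]


def test_merge_output_partitions_genome(rng):
    c = rng.poisson(20.0, 500).astype(float)
    steps = detect_steps(track(c), min_magnitude=1.0)
    ivs = merge_intervals(track(c), steps, sd_threshold=2.0)
    assert ivs[0].start == 0 and ivs[-1].end == 500
    for a, b in zip(ivs, ivs[1:]):
        assert a.end == b.start


def test_threshold_monotonicity(rng):
    c = np.concatenate([rng.poisson(m, 100) for m in (2, 50, 200, 10, 80)]).astype(float)
    steps = detect_steps(track(c), min_magnitude=2.0)
    counts = [len(merge_intervals(track(c), steps, sd_threshold=t)) for t in (0.5, 1.0, 2.0, 4.0, 8.0)]
    assert counts == sorted(counts, reverse=True)


def test_noise_free_boundaries_exact():
    c = np.concatenate([np.zeros(70), np.full(90, 55.0), np.zeros(60), np.full(80, 200.0)])
    tus = call_tus(track(c), smooth_window=1)
    assert [(t.start, t.end) for t in tus] == [(70, 160), (220, 300)]


def test_empty_track_errors():
    with pytest.raises(ValueError):
        merge_intervals(CoverageTrack("g", "both", "full_read", np.zeros(0)), [])


# --- call_transcription_units --------------------------------------------------


def test_single_block_tss_terminator_plus_strand():
    c = np.concatenate([np.zeros(100), np.full(100, 50.0), np.zeros(100)])
    tus = call_tus(track(c, strand="+"), smooth_window=1)
    (tu,) = tus
    assert (tu.start, tu.end) == (100, 200)
    assert tu.tss == 100 and tu.terminator == 200


def test_minus_strand_swaps_labels():
    c = np.concatenate([np.zeros(100), np.full(100, 50.0), np.zeros(100)])
    (tu,) = call_tus(track(c, strand="-"), smooth_window=1)
    assert tu.tss == 200 and tu.terminator == 100


def test_all_zero_no_tus():
    assert call_tus(track(np.zeros(300))) == []


def test_two_blocks_with_subthreshold_gap():
    c = np.zeros(300)
    c[20:120] = 60.0
    c[150:280] = 90.0  # gap 120..150 at zero
    tus = call_tus(track(c), smooth_window=1)
    assert [(t.start, t.end) for t in tus] == [(20, 120), (150, 280)]


def test_members_attached_by_overlap(two_gene_annotation):
    c = np.zeros(400)
    c[5:260] = 40.0
    (tu,) = call_tus(track(c), smooth_window=1, annotation=two_gene_annotation)
    assert tu.members == ["cdsA", "cdsB"]


# --- call_tss -------------------------------------------------------------------


def test_tss_single_spike_on_flat_background():
    c = np.ones(200)
    c[90] = 100.0
    (call,) = call_tss(track(c, mode="first_nucleotide"), window=50, k=5, min_height=10)
    assert call.pos == 90 and call.height == 100.0


def test_tss_small_spike_below_noise(rng):
    c = rng.poisson(1.0, 300).astype(float)
    c[150] = max(c.max(), 2.0)  # local max but within k*sd of the noise
    calls = call_tss(track(c, mode="first_nucleotide"), window=50, k=5, min_height=2)
    assert all(abs(t.pos - 150) > 0 for t in calls) or calls == []


def test_tss_window_suppression():
    c = np.ones(500)
    c[200], c[260] = 60.0, 70.0  # 60 nt apart: both
    calls = call_tss(track(c, mode="first_nucleotide"), window=50, k=5, min_height=10)
    assert [t.pos for t in calls] == [200, 260]
    c2 = np.ones(500)
    c2[200], c2[210] = 60.0, 70.0  # 10 nt apart: only the higher
    calls2 = call_tss(track(c2, mode="first_nucleotide"), window=50, k=5, min_height=10)
    assert [t.pos for t in calls2] == [210]


def test_tss_rejects_full_read_track():
    with pytest.raises(ValueError, match="first-nucleotide"):
        call_tss(track(np.ones(100), mode="full_read"))


def test_tss_rule_matches_direct_evaluation(rng):
    c = rng.poisson(2.0, 500).astype(float)
    for p in (60, 200, 390):
        c[p] = 80.0
    w, k, mh = 50, 5.0, 10.0
    got = {t.pos for t in call_tss(track(c, mode="first_nucleotide"), window=w, k=k, min_height=mh)}
    expect = set()
    for p in range(500):
        if c[p] < mh:
            continue
        lo, hi = max(0, p - w), min(500, p + w + 1)
        seg = np.delete(c[lo:hi], p - lo)
        if c[p] < c[lo:hi].max() or (c[lo:p] == c[p]).any():
            continue
        if c[p] > seg.mean() + k * seg.std():
            expect.add(p)
    assert got == expect == {60, 200, 390}
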