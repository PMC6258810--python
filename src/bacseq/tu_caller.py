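"""Transcription-unit, TSS and terminator calling from RNA-seq coverage.

The caller works in three stages, mirroring how a transcribed region looks in
a coverage plot.  First, candidate boundaries are found as local extremes of
the coverage derivative (sharp up-steps at transcription starts, down-steps at
terminators).  Second, the genome is split into the intervals between
candidate boundaries and adjacent intervals whose mean coverage does not
differ significantly are merged, iteratively removing the least significant
boundary until every surviving boundary separates genuinely different
coverage levels.  Third, maximal runs of intervals above an expression
threshold are reported as transcription units, with the entry (up) boundary
labeled TSS and the exit (down) boundary labeled terminator, strand-aware.

A separate single-nucleotide TSS caller operates on first-nucleotide coverage
from 5'-enriched libraries: a position is a TSS when it is the local maximum
of its window and rises above a dynamically estimated local noise level.

The significance rule for interval merging is pluggable; the default compares
the difference of interval means against a multiple of the larger interval
standard deviation.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .coverage import CoverageTrack
from .genome_io import Annotation

log = logging.getLogger(__name__)

# package-wide defaults, user-adjustable from every entry point
DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_MIN_MAGNITUDE = 5.0
DEFAULT_SD_THRESHOLD = 2.0
DEFAULT_SD_FLOOR = 1.0
DEFAULT_EXPRESSION_THRESHOLD = 10.0
DEFAULT_TSS_WINDOW = 50
DEFAULT_TSS_K = 5.0
DEFAULT_TSS_MIN_HEIGHT = 10.0


@dataclass
class ChangePoint:
    """A candidate boundary between positions pos-1 and pos."""

    pos: int
    direction: str  # 'up' (coverage increases left->right) or 'down'
    magnitude: float


@dataclass
class CoverageInterval:
    start: int
    end: int
    mean: float
    sd: float


@dataclass
class TranscriptionUnit:
    start: int
    end: int
    strand: str
    tss: int | None
    terminator: int | None
    mean_coverage: float
    members: list[str] = field(default_factory=list)


@dataclass
class TSSCall:
    pos: int
    strand: str
    height: float
    noise: float


# --- stage 1: step detection -------------------------------------------------


def detect_steps(
    track: CoverageTrack,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
) -> list[ChangePoint]:
    """Local extremes of the smoothed coverage derivative.

    Coverage is smoothed with a centered moving average of ``smooth_window``
    positions; the derivative d[i] = c̄[i] − c̄[i−1] is scanned for local
    extremes with |d| ≥ ``min_magnitude``.  Returned sorted by position.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    c = track.values
    if len(c) < smooth_window:
        raise ValueError("track shorter than smoothing window")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(c, kernel, mode="same")
    else:
        sm = c.astype(float)
    d = np.diff(sm)  # d[j] = boundary between positions j and j+1
    if len(d) == 0:
        return []
    steps: list[ChangePoint] = []
    # local extreme of d: |d[j]| >= |d[j-1]| and |d[j]| > |d[j+1]| with same sign run
    absd = np.abs(d)
    left_ok = np.empty(len(d), dtype=bool)
    right_ok = np.empty(len(d), dtype=bool)
    left_ok[0] = True
    left_ok[1:] = absd[1:] >= absd[:-1]
    right_ok[-1] = True
    right_ok[:-1] = absd[:-1] > absd[1:]
    cand = np.flatnonzero(left_ok & right_ok & (absd >= min_magnitude))
    for j in cand:
        steps.append(
            ChangePoint(pos=int(j) + 1, direction="up" if d[j] > 0 else "down", magnitude=float(d[j]))
        )
    return steps


# --- stage 2: significance-tested interval merging ---------------------------

SignificanceFn = Callable[[float, float, int, float, float, int], float]
# signature: (mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> significance statistic;
# the boundary is removable when the statistic is <= the threshold.


def sd_significance(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> float:
    """Default rule: |Δmean| in units of the larger interval SD (floored)."""
    return abs(mean_a - mean_b) / max(sd_a, sd_b, sd_floor)


def merge_intervals(
    track: CoverageTrack,
    steps: list[ChangePoint],
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    sd_floor: float = DEFAULT_SD_FLOOR,
    significance: SignificanceFn | None = None,
) -> list[CoverageInterval]:
    """Merge adjacent intervals whose coverage difference is insignificant.

    Starting from the partition induced by ``steps``, the boundary with the
    smallest significance statistic is removed (ties broken leftmost) and its
    two intervals joined; this repeats until every remaining boundary has a
    statistic above ``sd_threshold``.  The result always partitions [0, L).
    """
    c = track.values
    L = len(c)
    if L == 0:
        raise ValueError("empty coverage track")
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    sig = significance or (lambda ma, sa, na, mb, sb, nb: sd_significance(ma, sa, na, mb, sb, nb, sd_floor))

    # prefix sums give O(1) interval mean/sd
    cs = np.concatenate(([0.0], np.cumsum(c)))
    cs2 = np.concatenate(([0.0], np.cumsum(c * c)))

    def stats(i: int, j: int) -> tuple[float, float, int]:
        n = j - i
        mean = (cs[j] - cs[i]) / n
        var = max((cs2[j] - cs2[i]) / n - mean * mean, 0.0)
        return mean, float(np.sqrt(var)), n

    bounds = sorted({s.pos for s in steps if 0 < s.pos < L})
    pts = [0] + bounds + [L]
    m = len(pts)
    prev = list(range(-1, m - 1))
    nxt = list(range(1, m + 1))
    alive = [True] * m
    version = [0] * m

    def stat_at(k: int) -> float:
        i, j = pts[prev[k]], pts[k]
        j2 = pts[nxt[k]]
        return sig(*stats(i, j), *stats(j, j2))

    heap: list[tuple[float, int, int, int]] = []
    for k in range(1, m - 1):
        heapq.heappush(heap, (stat_at(k), pts[k], k, 0))

    while heap:
        z, _pos, k, ver = heapq.heappop(heap)
        if not alive[k] or ver != version[k] or k in (0, m - 1):
            continue
        if z > sd_threshold:
            break  # heap minimum is significant: all boundaries significant
        # remove boundary k, join neighbors, refresh adjacent entries
        alive[k] = False
        p, n = prev[k], nxt[k]
        nxt[p] = n
        prev[n] = p
        for nb in (p, n):
            if nb not in (0, m - 1) and alive[nb]:
                version[nb] += 1
                heapq.heappush(heap, (stat_at(nb), pts[nb], nb, version[nb]))

    out: list[CoverageInterval] = []
    k = 0
    while k != m - 1:
        j = nxt[k]
        mean, sd, _n = stats(pts[k], pts[j])
        out.append(CoverageInterval(start=pts[k], end=pts[j], mean=mean, sd=sd))
        k = j
    return out


# --- stage 3: transcription units --------------------------------------------


def call_transcription_units(
    intervals: list[CoverageInterval],
    track: CoverageTrack,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    annotation: Annotation | None = None,
) -> list[TranscriptionUnit]:
    """Assemble expressed interval runs into transcription units.

    A TU is a maximal run of consecutive intervals with mean coverage at or
    above ``expression_threshold``.  On the plus strand (and for unstranded
    tracks) the upstream low→high boundary is the TSS and the downstream
    high→low boundary the terminator; on the minus strand the labels swap.
    """
    strand = track.strand if track.strand in ("+", "-") else "+"
    tus: list[TranscriptionUnit] = []
    i = 0
    n = len(intervals)
    while i < n:
        if intervals[i].mean < expression_threshold:
            i += 1
            continue
        j = i
        while j + 1 < n and intervals[j + 1].mean >= expression_threshold:
            j += 1
        start, end = intervals[i].start, intervals[j].end
        w = sum((iv.end - iv.start) * iv.mean for iv in intervals[i : j + 1])
        mean_cov = w / (end - start)
        if strand == "-":
            tss, term = end, start
        else:
            tss, term = start, end
        members: list[str] = []
        if annotation is not None:
            members = [
                f.id
                for f in annotation.features
                if f.ftype in ("CDS", "gene") and f.start < end and f.end > start
            ]
        tus.append(
            TranscriptionUnit(
                start=start,
                end=end,
                strand=strand,
                tss=tss,
                terminator=term,
                mean_coverage=mean_cov,
                members=members,
            )
        )
        i = j + 1
    return tus


def call_tus(
    track: CoverageTrack,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    sd_floor: float = DEFAULT_SD_FLOOR,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    annotation: Annotation | None = None,
) -> list[TranscriptionUnit]:
    """Full pipeline: detect steps, merge intervals, call TUs."""
    steps = detect_steps(track, smooth_window, min_magnitude)
    intervals = merge_intervals(track, steps, sd_threshold, sd_floor)
    return call_transcription_units(intervals, track, expression_threshold, annotation)


# --- single-nucleotide TSS calling -------------------------------------------


def call_tss(
    track: CoverageTrack,
    window: int = DEFAULT_TSS_WINDOW,
    k: float = DEFAULT_TSS_K,
    min_height: float = DEFAULT_TSS_MIN_HEIGHT,
) -> list[TSSCall]:
    """Call single-base TSSs from first-nucleotide coverage.

    Position p is a TSS when c[p] is the maximum of [p−window, p+window]
    (leftmost wins on ties), c[p] ≥ ``min_height``, and c[p] exceeds the
    dynamic noise threshold mean + k·sd computed over the window excluding p.
    """
    if track.mode != "first_nucleotide":
        raise ValueError("first-nucleotide coverage required for TSS calling")
    if window < 1:
        raise ValueError("window must be >= 1")
    c = track.values
    L = len(c)
    strand = track.strand if track.strand in ("+", "-") else "+"
    cs = np.concatenate(([0.0], np.cumsum(c)))
    cs2 = np.concatenate(([0.0], np.cumsum(c * c)))
    calls: list[TSSCall] = []
    for p in np.flatnonzero(c >= min_height):
        lo, hi = max(0, p - window), min(L, p + window + 1)
        seg = c[lo:hi]
        if c[p] < seg.max():
            continue
        if (seg[: p - lo] == c[p]).any():  # leftmost of ties
            continue
        n = hi - lo - 1
        if n <= 1:
            continue
        total = cs[hi] - cs[lo] - c[p]
        total2 = cs2[hi] - cs2[lo] - c[p] * c[p]
        mean = total / n
        var = max(total2 / n - mean * mean, 0.0)
        noise = mean + k * float(np.sqrt(var))
        if c[p] > noise:
            calls.append(TSSCall(pos=int(p), strand=strand, height=float(c[p]), noise=float(noise)))
    return calls


# --- export ------------------------------------------------------------------


def tus_to_annotation(tus: list[TranscriptionUnit], genome_id: str) -> Annotation:
    """Convert TU calls into TU/TSS/terminator features for GFF3/BED export."""
    from .genome_io import Feature

    ann = Annotation(genome_id=genome_id)
    for i, tu in enumerate(tus, 1):
        ann.features.append(
            Feature(
                id=f"TU_{i}",
                ftype="TU",
                start=tu.start,
                end=tu.end,
                strand=tu.strand,
                qualifiers={"mean_coverage": f"{tu.mean_coverage:.2f}",
                            "members": ",".join(tu.members)},
            )
        )
        if tu.tss is not None:
            pos = min(tu.tss, tu.end - 1) if tu.tss >= tu.end else tu.tss
            ann.features.append(
                Feature(id=f"TSS_{i}", ftype="TSS", start=pos, end=pos + 1, strand=tu.strand)
            )
        if tu.terminator is not None:
            pos = min(tu.terminator, tu.end - 1) if tu.terminator >= tu.end else tu.terminator
            ann.features.append(
                Feature(id=f"term_{i}", ftype="terminator", start=pos, end=pos + 1, strand=tu.strand)
            )
    ann.sort()
    return ann


def write_bed(tus: list[TranscriptionUnit], genome_id: str, path) -> None:
    with open(path, "w") as fh:
        for i, tu in enumerate(tus, 1):
            fh.write(
                f"{genome_id}\t{tu.start}\t{tu.end}\tTU_{i}\t"
                f"{min(int(round(tu.mean_coverage)), 1000)}\t{tu.strand}\n"
            )
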