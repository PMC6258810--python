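"""Position weight matrices: construction from aligned sites, logo statistics,
genome scanning and de novo motif discovery by expectation-maximization.

Scanning supports two scores: the frequency sum Σ_j f[base_j, j] (bounded by
the motif width) and the log-odds sum Σ_j log2(f/background).  De novo search
runs a one-occurrence-per-sequence EM from several seeded k-mer starts and
returns the highest-likelihood motif.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeSequence, reverse_complement

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM = np.full(4, 0.25)


@dataclass
class PWM:
    """4×width base-frequency matrix (rows A, C, G, T; columns sum to 1)."""

    freqs: np.ndarray
    name: str = "pwm"
    pseudocount: float = 0.5
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freqs.shape[0] != 4:
            raise ValueError("freqs must have 4 rows (A, C, G, T)")
        if not np.allclose(self.freqs.sum(axis=0), 1.0):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=0))

    def max_score(self, scoring: str = "frequency_sum") -> float:
        if scoring == "frequency_sum":
            return float(self.freqs.max(axis=0).sum())
        return float(np.log2(self.freqs / self.background[:, None]).max(axis=0).sum())


@dataclass
class LogoColumn:
    pos: int
    entropy_bits: float
    info_bits: float
    loglik: np.ndarray  # per-base log2(f / background)


@dataclass
class MotifHit:
    pos: int
    strand: str
    score: float
    site: str


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; anything else to 4 (treated as unscorable)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def base_composition(seqs) -> np.ndarray:
    """Background base frequencies of one or more sequences."""
    if isinstance(seqs, (str, GenomeSequence)):
        seqs = [seqs]
    counts = np.zeros(4)
    for s in seqs:
        codes = _encode(s.seq if isinstance(s, GenomeSequence) else str(s))
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM.copy()
    return counts / counts.sum()


def logo_columns(pwm: PWM) -> list[LogoColumn]:
    cols = []
    for j in range(pwm.width):
        f = pwm.freqs[:, j]
        nz = f > 0
        h = float(-(f[nz] * np.log2(f[nz])).sum())
        cols.append(
            LogoColumn(
                pos=j,
                entropy_bits=h,
                info_bits=2.0 - h,
                loglik=np.log2(np.maximum(f, 1e-300) / pwm.background),
            )
        )
    return cols


def build_pwm(
    aligned_sites: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> tuple[PWM, list[LogoColumn]]:
    """Build a PWM from equal-length aligned sites.

    freqs[b, j] = (count[b, j] + pseudocount) / (n + 4·pseudocount).
    Returns the PWM together with its per-column logo statistics (Shannon
    entropy, information content, per-base log-likelihood).
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    w = len(aligned_sites[0])
    if any(len(s) != w for s in aligned_sites):
        raise ValueError("aligned sites must all have the same length")
    counts = np.zeros((4, w))
    for s in aligned_sites:
        codes = _encode(s)
        if (codes >= 4).any():
            raise ValueError(f"site {s!r} contains non-ACGT symbols")
        counts[codes, np.arange(w)] += 1
    n = len(aligned_sites)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.asarray(background, dtype=float) if background is not None else UNIFORM.copy()
    pwm = PWM(freqs=freqs, name=name, pseudocount=pseudocount, background=bg)
    return pwm, logo_columns(pwm)


# --- plain-text PWM format ---------------------------------------------------


def write_pwm(pwm: PWM, path) -> None:
    """Text format: header '#PWM name width', then labeled A/C/G/T rows."""
    with open(path, "w") as fh:
        fh.write(f"#PWM {pwm.name} {pwm.width}\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(f"{v:.6g}" for v in pwm.freqs[i]) + "\n")


def read_pwm(path) -> PWM:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[0] != "#PWM":
            raise ValueError(f"{path}: expected header '#PWM name width'")
        name, width = header[1], int(header[2])
        rows = {}
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    freqs = np.array([rows[b] for b in BASES])
    if freqs.shape != (4, width):
        raise ValueError(f"{path}: matrix shape {freqs.shape} does not match header width {width}")
    freqs = freqs / freqs.sum(axis=0)  # renormalize against rounding
    return PWM(freqs=freqs, name=name)


# --- scanning ----------------------------------------------------------------


def _window_scores(codes: np.ndarray, score_matrix: np.ndarray, w: int) -> np.ndarray:
    """Score every window; windows containing non-ACGT become -inf."""
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    valid = codes < 4
    safe = np.where(valid, codes, 0)
    scores = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for j in range(w):
        scores += score_matrix[safe[j : j + n], j]
        ok &= valid[j : j + n]
    scores[~ok] = -np.inf
    return scores


def scan_pwm(
    genome,
    pwm: PWM,
    threshold: float,
    scoring: str = "frequency_sum",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All PWM matches with score ≥ threshold, sorted by position.

    Reverse-strand hits are reported at the forward-strand coordinate of the
    site's left edge.  A threshold above the maximum attainable score yields
    an empty result with a warning stating that maximum.
    """
    if scoring not in ("frequency_sum", "log_odds"):
        raise ValueError("scoring must be 'frequency_sum' or 'log_odds'")
    seq = (genome.seq if isinstance(genome, GenomeSequence) else str(genome)).upper()
    w = pwm.width
    if len(seq) < w:
        raise ValueError("sequence shorter than PWM width")
    max_score = pwm.max_score(scoring)
    if threshold > max_score:
        warnings.warn(
            f"threshold {threshold} exceeds the maximum attainable {scoring} score {max_score:.4g}"
        )
        return []
    if scoring == "frequency_sum":
        sm = pwm.freqs
    else:
        sm = np.log2(np.maximum(pwm.freqs, 1e-300) / pwm.background[:, None])
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        s = seq if strand == "+" else reverse_complement(seq)
        scores = _window_scores(_encode(s), sm, w)
        for p in np.flatnonzero(scores >= threshold):
            p = int(p)
            fwd = p if strand == "+" else len(seq) - p - w
            hits.append(MotifHit(pos=fwd, strand=strand, score=float(scores[p]), site=s[p : p + w]))
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


# --- de novo discovery (OOPS EM) ---------------------------------------------


def _em_once(
    codes: list[np.ndarray],
    width: int,
    init_freqs: np.ndarray,
    background: np.ndarray,
    pseudocount: float,
    max_iter: int,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, list[float]]:
    """One EM run of the one-occurrence-per-sequence model."""
    freqs = init_freqs.copy()
    log_bg = np.log(background)
    ll_history: list[float] = []
    for _ in range(max_iter):
        expected = np.full((4, width), pseudocount)
        total_ll = 0.0
        posteriors = []
        for c in codes:
            n = len(c) - width + 1
            logp = np.zeros(n)
            lf = np.log(np.maximum(freqs, 1e-300))
            bg_ll = float(log_bg[c].sum())
            for j in range(width):
                logp += lf[c[j : j + n], j] - log_bg[c[j : j + n]]
            m = logp.max()
            z = np.exp(logp - m)
            post = z / z.sum()
            total_ll += bg_ll + m + np.log(z.sum()) - np.log(n)
            posteriors.append(post)
        ll_history.append(total_ll)
        for c, post in zip(codes, posteriors):
            n = len(post)
            for j in range(width):
                np.add.at(expected[:, j], c[j : j + n], post)
        freqs = expected / expected.sum(axis=0)
        if len(ll_history) > 1 and abs(ll_history[-1] - ll_history[-2]) < tol:
            break
    return freqs, ll_history[-1], ll_history


@dataclass
class DenovoResult:
    pwm: PWM
    assignments: list[int]  # most likely site start per sequence
    log_likelihood: float
    ll_history: list[float]


def denovo_motif(
    seqs: list[str],
    width: int,
    n_starts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> DenovoResult:
    """Find one motif of fixed width shared by every sequence (OOPS EM).

    Each restart initializes the PWM from a randomly chosen k-mer (70% weight
    on the observed base); the best run by final log-likelihood wins.
    Deterministic for a given seed.
    """
    seqs = [str(s).upper() for s in seqs]
    if any(len(s) < width for s in seqs):
        raise ValueError("every sequence must be at least as long as the motif width")
    codes = [_encode(s) for s in seqs]
    if any((c >= 4).any() for c in codes):
        raise ValueError("sequences must be ACGT only")
    bg = np.asarray(background, dtype=float) if background is not None else base_composition(seqs)
    bg = np.maximum(bg, 1e-6)
    bg = bg / bg.sum()
    rng = np.random.default_rng(seed)
    # candidate starts: every k-mer position of a randomly chosen anchor
    # sequence plus random k-mers from the others, screened by a short EM run
    anchor = int(rng.integers(len(seqs)))
    starts = [(anchor, p) for p in range(len(seqs[anchor]) - width + 1)]
    for _ in range(n_starts):
        si = int(rng.integers(len(seqs)))
        starts.append((si, int(rng.integers(len(seqs[si]) - width + 1))))
    screened: list[tuple[float, np.ndarray]] = []
    for si, pos in starts:
        kmer = codes[si][pos : pos + width]
        init = np.full((4, width), 0.1)
        init[kmer, np.arange(width)] = 0.7
        freqs, ll, _ = _em_once(codes, width, init, bg, pseudocount, max_iter=3)
        screened.append((ll, freqs))
    screened.sort(key=lambda t: -t[0])
    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ll, init_freqs in screened[: max(3, n_starts // 3)]:
        freqs, ll, hist = _em_once(codes, width, init_freqs, bg, pseudocount, max_iter)
        if best is None or ll > best[0]:
            best = (ll, freqs, hist)
    ll, freqs, hist = best
    pwm = PWM(freqs=freqs, name=f"denovo_w{width}", pseudocount=pseudocount, background=bg)
    lf = np.log(np.maximum(freqs, 1e-300))
    log_bg = np.log(bg)
    assignments = []
    for c in codes:
        n = len(c) - width + 1
        logp = np.zeros(n)
        for j in range(width):
            logp += lf[c[j : j + n], j] - log_bg[c[j : j + n]]
        assignments.append(int(np.argmax(logp)))
    return DenovoResult(pwm=pwm, assignments=assignments, log_likelihood=ll, ll_history=hist)
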