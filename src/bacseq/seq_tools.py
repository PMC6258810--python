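"""Sequence-composition and pattern analyses.

GC content/skew profiles, codon usage tables, six-frame ORF prediction,
k-word seeded similarity search with Needleman–Wunsch gap closing, exact
direct/inverted repeat finding and IUPAC-aware restriction mapping.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable

from .genome_io import Annotation, Feature, GenomeSequence, feature_sequence, reverse_complement

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class WindowProfile:
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray


@dataclass
class AlignmentHit:
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    score: float
    aligned_query: str
    aligned_subject: str


@dataclass
class RepeatHit:
    pos1: int
    pos2: int
    unit_len: int
    spacer: int
    kind: str  # 'direct' or 'inverted'


# --- composition -------------------------------------------------------------


def _seq_of(genome) -> str:
    return genome.seq if isinstance(genome, GenomeSequence) else str(genome)


def gc_profile(
    genome,
    window: int = 200,
    step: int = 1,
    kind: str = "content",
    circular: bool = False,
) -> WindowProfile:
    """Windowed GC content ((G+C)/window) or GC skew ((G−C)/(G+C), 0 if G+C=0)."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if kind not in ("content", "skew"):
        raise ValueError("kind must be 'content' or 'skew'")
    seq = _seq_of(genome).upper()
    L = len(seq)
    if circular:
        seq = seq + seq[: window - 1]
        starts = np.arange(0, L, step)
    elif window > L:
        warnings.warn(f"window {window} exceeds sequence length {L}; using one truncated window")
        starts = np.array([0])
        window = L
    else:
        starts = np.arange(0, L - window + 1, step)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = (a == ord("G")).astype(np.int32)
    is_c = (a == ord("C")).astype(np.int32)
    cg = np.concatenate(([0], np.cumsum(is_g)))
    cc = np.concatenate(([0], np.cumsum(is_c)))
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    if kind == "content":
        values = (g + c) / window
    else:
        denom = g + c
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return WindowProfile(window=window, step=step, starts=starts, values=values.astype(float))


_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]


def codon_to_aa(codon: str) -> str:
    codon = codon.upper()
    if codon in _BACTERIAL.stop_codons:
        return "*"
    return _BACTERIAL.forward_table.get(codon, "X")


def codon_usage(annotation: Annotation, genome: GenomeSequence) -> pd.DataFrame:
    """Codon counts over all CDSs with per-amino-acid fractions.

    Fractions sum to 1 within each amino-acid family; stop codons form their
    own ``*`` family.  Incomplete trailing codons are ignored.
    """
    cds = annotation.by_type("CDS")
    if not cds:
        raise ValueError("annotation contains no CDS features")
    counts: dict[str, int] = {}
    for f in cds:
        seq = feature_sequence(f, genome)
        for i in range(0, 3 * (len(seq) // 3), 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
    rows = []
    for codon in sorted(counts):
        rows.append({"codon": codon, "aa": codon_to_aa(codon), "count": counts[codon]})
    df = pd.DataFrame(rows)
    totals = df.groupby("aa")["count"].transform("sum")
    df["fraction"] = df["count"] / totals
    return df


# --- ORF prediction ----------------------------------------------------------

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})


def _orfs_one_strand(seq: str, L: int, min_len: int, start_codons, strand: str, circular: bool):
    """ORFs on one strand of a (possibly origin-extended) sequence.

    One ORF per stop: from the first start codon following the previous
    in-frame stop to the stop codon inclusive.
    """
    out = []
    n = len(seq)
    for frame in range(3):
        region_start = None  # first start codon since last stop
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if region_start is not None:
                    length = i + 3 - region_start
                    if length >= min_len and (not circular or region_start < L) and length <= L:
                        out.append((region_start, i + 3, strand))
                region_start = None
            elif region_start is None and codon in start_codons:
                region_start = i
    return out


def find_orfs(
    genome,
    min_len: int = 90,
    start_codons=DEFAULT_START_CODONS,
    circular: bool | None = None,
) -> list[Feature]:
    """Six-frame ORF prediction (start codon to in-frame stop, stop included).

    On circular genomes the scan is extended across the origin.  Coordinates
    of minus-strand ORFs are reported on the forward strand, 0-based
    half-open; origin-spanning ORFs get explicit two-part locations.
    """
    if min_len < 6:
        raise ValueError("min_len must be >= 6")
    if isinstance(genome, GenomeSequence):
        seq = genome.seq
        circ = genome.circular if circular is None else circular
    else:
        seq = str(genome).upper()
        circ = bool(circular)
    L = len(seq)
    scan = seq + seq[: L - 1] if circ else seq
    raw = _orfs_one_strand(scan, L, min_len, start_codons, "+", circ)
    rc = reverse_complement(seq)
    scan_rc = rc + rc[: L - 1] if circ else rc
    raw += _orfs_one_strand(scan_rc, L, min_len, start_codons, "-", circ)
    feats: list[Feature] = []
    seen = set()
    for s, e, strand in sorted(raw):
        length = e - s
        if strand == "-":
            # rc index i maps to forward index (L-1-i) mod L; an rc interval
            # maps to the forward interval starting at (L - e) mod L
            s_mod = (L - e) % L if circ else L - e
        else:
            s_mod = s % L if circ else s
        e_mod = s_mod + length
        key = (s_mod % L, (e_mod - s_mod), strand)
        if key in seen:
            continue
        seen.add(key)
        if e_mod <= L:
            feats.append(Feature(id=f"orf_{len(feats)+1}", ftype="CDS", start=s_mod, end=e_mod,
                                 strand=strand, qualifiers={"tool": "find_orfs"}))
        else:
            parts = [(s_mod, L), (0, e_mod - L)]
            feats.append(Feature(id=f"orf_{len(feats)+1}", ftype="CDS", start=s_mod, end=L,
                                 strand=strand, qualifiers={"tool": "find_orfs"}, parts=parts))
    feats.sort(key=lambda f: (f.start, f.end, f.strand))
    for i, f in enumerate(feats, 1):
        f.id = f"orf_{i}"
    return feats


# --- k-word seeded search ----------------------------------------------------


def _global_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _identity(a: str, b: str) -> float:
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a) if a else 0.0


def _chain_hits(query: str, subject: str, k: int, aligner) -> list[tuple[int, int, int, int]]:
    """Seed and chain: co-diagonal k-word seeds merged into candidate regions."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for j in range(len(subject) - k + 1):
        for i in index.get(subject[j : j + k], ()):
            by_diag.setdefault(j - i, []).append(i)
    regions = []
    max_gap = 10 * k  # seeds farther apart than this start a new chain
    for diag, qpos in by_diag.items():
        qpos.sort()
        cs = qpos[0]
        ce = qpos[0] + k
        for i in qpos[1:]:
            if i <= ce + max_gap:
                ce = max(ce, i + k)
            else:
                regions.append((cs, ce, cs + diag, ce + diag))
                cs, ce = i, i + k
        regions.append((cs, ce, cs + diag, ce + diag))
    return regions


def kword_search(
    query,
    subject,
    k: int = 11,
    min_identity: float = 0.8,
    min_len: int | None = None,
    both_strands: bool = False,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[AlignmentHit]:
    """Find similar regions by k-word seeding plus Needleman–Wunsch closing.

    The query is k-mer indexed; subject matches on a shared diagonal are
    chained into candidate regions, each region is globally aligned, and hits
    below ``min_identity`` or ``min_len`` (default: query length // 2) are
    discarded.  With ``both_strands`` the reverse complement of the query is
    searched too; minus-strand hits carry forward-strand query coordinates.
    """
    query = _seq_of(query).upper()
    subject = _seq_of(subject).upper()
    if k < 4:
        raise ValueError("k must be >= 4")
    if len(query) < k:
        raise ValueError("query shorter than k")
    if min_len is None:
        min_len = max(k, len(query) // 2)
    aligner = _global_aligner(match, mismatch, gap)
    hits: list[AlignmentHit] = []
    for strand, q in (("+", query), ("-", reverse_complement(query))) if both_strands else (("+", query),):
        for qs, qe, ss_, se_ in _chain_hits(q, subject, k, aligner):
            ss_, se_ = max(ss_, 0), min(se_, len(subject))
            if qe - qs < min_len and se_ - ss_ < min_len:
                continue
            aln = aligner.align(q[qs:qe], subject[ss_:se_])[0]
            a_q, a_s = str(aln[0]), str(aln[1])
            ident = _identity(a_q, a_s)
            if ident < min_identity or len(a_q) < min_len:
                continue
            if strand == "-":
                q_start, q_end = len(query) - qe, len(query) - qs
            else:
                q_start, q_end = qs, qe
            hits.append(
                AlignmentHit(
                    q_start=q_start, q_end=q_end, s_start=ss_, s_end=se_,
                    strand=strand, identity=ident, score=float(aln.score),
                    aligned_query=a_q, aligned_subject=a_s,
                )
            )
    # deduplicate overlapping hits, keep highest score
    hits.sort(key=lambda h: -h.score)
    kept: list[AlignmentHit] = []
    for h in hits:
        if any(
            h.strand == o.strand
            and h.s_start < o.s_end and o.s_start < h.s_end
            and h.q_start < o.q_end and o.q_start < h.q_end
            for o in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.s_start, h.q_start))
    return kept


# --- repeats -----------------------------------------------------------------

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_x] = _y


def find_repeats(
    seq,
    unit_len: int,
    max_spacer: int,
    kind: str = "both",
) -> list[RepeatHit]:
    """Exact direct/inverted repeats: two N-mers separated by a 0..K spacer.

    A direct repeat requires the second unit to equal the first; an inverted
    repeat requires it to equal the reverse complement of the first.
    """
    if unit_len < 3:
        raise ValueError("unit_len must be >= 3")
    if kind not in ("direct", "inverted", "both"):
        raise ValueError("kind must be 'direct', 'inverted' or 'both'")
    s = _seq_of(seq).upper()
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    L = len(a)
    N = unit_len
    comp = _COMP_TABLE[a]
    hits: list[RepeatHit] = []
    for K in range(0, max_spacer + 1):
        span = 2 * N + K
        if span > L:
            break
        n_pos = L - span + 1
        if kind in ("direct", "both"):
            m = np.ones(n_pos, dtype=bool)
            for j in range(N):
                m &= a[j : j + n_pos] == a[N + K + j : N + K + j + n_pos]
            for p in np.flatnonzero(m):
                hits.append(RepeatHit(pos1=int(p), pos2=int(p) + N + K, unit_len=N, spacer=K, kind="direct"))
        if kind in ("inverted", "both"):
            m = np.ones(n_pos, dtype=bool)
            for j in range(N):
                # second unit reverse-complement equals first unit
                m &= a[j : j + n_pos] == comp[N + K + N - 1 - j : N + K + N - 1 - j + n_pos]
            for p in np.flatnonzero(m):
                hits.append(RepeatHit(pos1=int(p), pos2=int(p) + N + K, unit_len=N, spacer=K, kind="inverted"))
    hits.sort(key=lambda h: (h.pos1, h.spacer, h.kind))
    return hits


# --- restriction mapping -----------------------------------------------------


def iupac_regex(site: str) -> str:
    out = []
    for ch in site.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in site {site!r}")
        opts = IUPAC[ch]
        out.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(out)


def load_enzymes(path=None) -> dict[str, str]:
    """Load the enzyme table (name<TAB>site); default: bundled table."""
    if path is None:
        src = resources.files("bacseq").joinpath("data").joinpath("enzymes.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    enzymes = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site = line.split("\t")[:2]
        enzymes[name] = site.upper()
    return enzymes


def restriction_map(
    genome,
    enzymes: dict[str, str] | None = None,
    circular: bool | None = None,
) -> list[tuple[str, int, str]]:
    """All recognition-site occurrences of each enzyme, both strands.

    Positions are the 0-based forward-strand start of the site; palindromic
    sites are reported once (on '+').  Circular sequences are scanned across
    the origin.
    """
    if isinstance(genome, GenomeSequence):
        seq = genome.seq
        circ = genome.circular if circular is None else circular
    else:
        seq = str(genome).upper()
        circ = bool(circular)
    if enzymes is None:
        enzymes = load_enzymes()
    L = len(seq)
    out: list[tuple[str, int, str]] = []
    for name, site in enzymes.items():
        w = len(site)
        scan = seq + seq[: w - 1] if circ and L >= w else seq
        pat = re.compile(f"(?=({iupac_regex(site)}))")
        fwd = {m.start() % L if circ else m.start() for m in pat.finditer(scan)}
        for p in fwd:
            out.append((name, p, "+"))
        if site != reverse_complement(site):
            pat_rc = re.compile(f"(?=({iupac_regex(reverse_complement(site))}))")
            for m in pat_rc.finditer(scan):
                p = m.start() % L if circ else m.start()
                out.append((name, p, "-"))
    out.sort(key=lambda t: (t[1], t[0], t[2]))
    return out
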