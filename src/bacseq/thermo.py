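"""Nearest-neighbor thermodynamics for DNA oligonucleotides and RNA hairpins.

Duplex enthalpy and entropy are summed over dinucleotide propagation steps
plus initiation/terminal corrections from editable parameter tables (unified
DNA set; RNA Watson-Crick set with size-dependent hairpin loop penalties).
Melting temperature follows the bimolecular two-state formula
Tm = 1000·ΔH / (ΔS + R·ln(C_T/x)) − 273.15 with x = 4 for non-self-
complementary duplexes and x = 1 for self-complementary ones.

Oligo cross-dimers and hairpins are found by iterative annealing: one strand
(or the oligo's 3' arm) is slid against the other across all offsets, maximal
complementary runs are stacked with the nearest-neighbor table, and the most
stable structures are reported.  Genome-wide hairpin scanning applies the
same fold scoring with RNA parameters inside a sliding window, which is how
intrinsic terminator candidates show up.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .genome_io import GenomeSequence, reverse_complement

log = logging.getLogger(__name__)

R_GAS = 1.9872  # cal/(mol*K)
T37 = 310.15  # K
DEFAULT_CONC = 0.25e-6  # molar single-strand concentration


@dataclass
class NNTable:
    alphabet: str  # 'DNA' or 'RNA'
    dH: dict[str, float]
    dS: dict[str, float]
    init_terms: dict[str, tuple[float, float]]
    loop_dG37: dict[int, float] = field(default_factory=dict)
    loop_default_dG37: float | None = None

    def loop_penalty(self, size: int) -> float:
        """Hairpin loop initiation dG37 (kcal/mol) for a loop of ``size`` nt."""
        if size < 3:
            raise ValueError("hairpin loops must be >= 3 nt")
        if size in self.loop_dG37:
            return self.loop_dG37[size]
        if self.loop_dG37:
            nmax = max(self.loop_dG37)
            # Jacobson-Stockmayer extrapolation beyond the tabulated sizes
            return self.loop_dG37[nmax] + 1.75 * R_GAS * T37 / 1000 * math.log(size / nmax)
        if self.loop_default_dG37 is not None:
            return self.loop_default_dG37
        raise ValueError("table carries no hairpin loop parameters")


@dataclass
class ThermoResult:
    dH: float  # kcal/mol
    dS: float  # cal/(mol*K)
    dG37: float  # kcal/mol
    tm: float  # Celsius


@dataclass
class DuplexStructure:
    offset: int
    paired: list[tuple[int, int]]
    result: ThermoResult


@dataclass
class HairpinCandidate:
    pos: int
    stem_len: int
    loop_len: int
    dG: float
    strand: str


def load_nn_table(alphabet: str = "DNA", path=None) -> NNTable:
    """Load a nearest-neighbor parameter table from TSV (bundled by default)."""
    alphabet = alphabet.upper()
    if alphabet not in ("DNA", "RNA"):
        raise ValueError("alphabet must be 'DNA' or 'RNA'")
    if path is None:
        name = "nn_dna.tsv" if alphabet == "DNA" else "nn_rna.tsv"
        text = resources.files("bacseq").joinpath("data").joinpath(name).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    dH: dict[str, float] = {}
    dS: dict[str, float] = {}
    init: dict[str, tuple[float, float]] = {}
    loops: dict[int, float] = {}
    loop_default = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, h, s = line.split("\t")[:3]
        if key.startswith("hairpin_dG37_"):
            loops[int(key.rsplit("_", 1)[1])] = float(h)
        elif key == "hairpin_loop_dG37":
            loop_default = float(h)
        elif len(key) == 2 and key.isalpha() and key.isupper():
            dH[key] = float(h)
            dS[key] = float(s)
        else:
            init[key] = (float(h), float(s))
    missing = {a + b for a in "ACG" + ("T" if alphabet == "DNA" else "U") for b in "ACG" + ("T" if alphabet == "DNA" else "U")} - set(dH)
    if missing:
        raise ValueError(f"NN table incomplete: missing steps {sorted(missing)}")
    return NNTable(alphabet=alphabet, dH=dH, dS=dS, init_terms=init,
                   loop_dG37=loops, loop_default_dG37=loop_default)


_DNA_TABLE: NNTable | None = None
_RNA_TABLE: NNTable | None = None


def default_table(alphabet: str = "DNA") -> NNTable:
    global _DNA_TABLE, _RNA_TABLE
    if alphabet.upper() == "DNA":
        if _DNA_TABLE is None:
            _DNA_TABLE = load_nn_table("DNA")
        return _DNA_TABLE
    if _RNA_TABLE is None:
        _RNA_TABLE = load_nn_table("RNA")
    return _RNA_TABLE


def _norm_seq(seq: str, table: NNTable) -> str:
    seq = seq.upper()
    if table.alphabet == "RNA":
        seq = seq.replace("T", "U")
        alphabet = set("ACGU")
    else:
        seq = seq.replace("U", "T")
        alphabet = set("ACGT")
    if not seq or set(seq) - alphabet:
        raise ValueError(f"sequence must be non-empty over {sorted(alphabet)}: {seq!r}")
    return seq


def _is_self_complementary(seq: str, table: NNTable) -> bool:
    if table.alphabet == "RNA":
        comp = str.maketrans("ACGU", "UGCA")
        return seq == seq.translate(comp)[::-1]
    return seq == reverse_complement(seq)


def _stack_sum(seq: str, table: NNTable) -> tuple[float, float]:
    dh = sum(table.dH[seq[i : i + 2]] for i in range(len(seq) - 1))
    ds = sum(table.dS[seq[i : i + 2]] for i in range(len(seq) - 1))
    return dh, ds


def _terminal_terms(seq: str, table: NNTable) -> tuple[float, float]:
    dh = ds = 0.0
    if table.alphabet == "DNA":
        for base in (seq[0], seq[-1]):
            key = "init_GC" if base in "GC" else "init_AT"
            h, s = table.init_terms[key]
            dh += h
            ds += s
    else:
        h, s = table.init_terms["init"]
        dh += h
        ds += s
        for base in (seq[0], seq[-1]):
            if base in "AU":
                h, s = table.init_terms["term_AU"]
                dh += h
                ds += s
    return dh, ds


def _make_result(dh: float, ds: float, conc: float | None, x: float = 4.0) -> ThermoResult:
    dg37 = dh - T37 * ds / 1000.0
    if conc is None:  # unimolecular (hairpin)
        tm = 1000.0 * dh / ds - 273.15 if ds != 0 else float("nan")
    else:
        denom = ds + R_GAS * math.log(conc / x)
        tm = 1000.0 * dh / denom - 273.15 if denom != 0 else float("nan")
    return ThermoResult(dH=dh, dS=ds, dG37=dg37, tm=tm)


def duplex_thermo(
    seq: str,
    table: NNTable | None = None,
    oligo_conc: float = DEFAULT_CONC,
    salt_molar: float | None = None,
) -> ThermoResult:
    """Thermodynamics of an oligo bound to its perfect complement.

    ΔH/ΔS are the nearest-neighbor propagation sums plus initiation terms
    (and the symmetry correction for self-complementary oligos).  An optional
    monovalent-salt entropy correction (0.368·(N−1)·ln[Na+] per duplex) can
    be applied; the default is the table's reference salt condition.
    """
    table = table or default_table("DNA")
    seq = _norm_seq(seq, table)
    if len(seq) < 2:
        raise ValueError("need at least 2 nt for nearest-neighbor calculation")
    dh, ds = _stack_sum(seq, table)
    th, ts = _terminal_terms(seq, table)
    dh += th
    ds += ts
    selfcomp = _is_self_complementary(seq, table)
    if selfcomp:
        h, s = table.init_terms.get("symmetry", (0.0, -1.4))
        dh += h
        ds += s
    if salt_molar is not None:
        ds += 0.368 * (len(seq) - 1) * math.log(salt_molar)
    return _make_result(dh, ds, oligo_conc, x=1.0 if selfcomp else 4.0)


# --- dimers and hairpins -----------------------------------------------------

_PAIRS_DNA = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIRS_RNA = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _pairs(table: NNTable):
    return _PAIRS_RNA if table.alphabet == "RNA" else _PAIRS_DNA


def _run_thermo(run_seq: str, table: NNTable) -> tuple[float, float]:
    """Stacking + run-end terms for one contiguous paired run."""
    dh, ds = _stack_sum(run_seq, table)
    th, ts = _terminal_terms(run_seq, table)
    return dh + th, ds + ts


def oligo_dimers(
    a: str,
    b: str,
    table: NNTable | None = None,
    top_n: int = 3,
    min_run: int = 2,
    oligo_conc: float = DEFAULT_CONC,
) -> list[DuplexStructure]:
    """Most stable antiparallel cross-dimer structures of two oligos.

    ``b`` is slid against ``a`` over every offset; at each offset the maximal
    complementary runs (length ≥ ``min_run``) are scored with nearest-neighbor
    stacking plus run-end initiation.  Structures are returned most negative
    ΔG37 first.  ``paired`` holds (index in a, index in b) pairs.
    """
    table = table or default_table("DNA")
    a = _norm_seq(a, table)
    b = _norm_seq(b, table)
    pairs = _pairs(table)
    rb = b[::-1]  # antiparallel: a left-to-right vs b right-to-left
    structures: list[DuplexStructure] = []
    for offset in range(-(len(rb) - 1), len(a)):
        paired: list[tuple[int, int]] = []
        runs: list[list[int]] = []
        current: list[int] = []
        for i in range(max(0, offset), min(len(a), offset + len(rb))):
            j = i - offset  # index into rb
            if (a[i], rb[j]) in pairs:
                current.append(i)
            else:
                if len(current) >= min_run:
                    runs.append(current)
                current = []
        if len(current) >= min_run:
            runs.append(current)
        if not runs:
            continue
        dh = ds = 0.0
        for run in runs:
            h, s = _run_thermo(a[run[0] : run[-1] + 1], table)
            dh += h
            ds += s
            paired.extend((i, len(b) - 1 - (i - offset)) for i in run)
        structures.append(
            DuplexStructure(offset=offset, paired=paired, result=_make_result(dh, ds, oligo_conc))
        )
    structures.sort(key=lambda st: st.result.dG37)
    return structures[:top_n]


def _hairpin_structures(
    seq: str,
    table: NNTable,
    min_stem: int = 2,
    min_loop: int = 3,
    max_loop: int | None = None,
) -> list[DuplexStructure]:
    """Enumerate fully complementary stems with loop >= min_loop, scored."""
    pairs = _pairs(table)
    L = len(seq)
    out: list[DuplexStructure] = []
    for i in range(L):
        for s in range(min_stem, (L - i - min_loop) // 2 + 1):
            # stem: seq[i:i+s] pairs seq[j0:j0+s] reversed, loop between
            max_j0 = L - s
            for loop in range(min_loop, (max_loop if max_loop is not None else L)):
                j0 = i + s + loop
                if j0 > max_j0:
                    break
                if all((seq[i + t], seq[j0 + s - 1 - t]) in pairs for t in range(s)):
                    dh, ds = _stack_sum(seq[i : i + s], table)
                    dg_loop = table.loop_penalty(loop)
                    ds += -dg_loop * 1000.0 / T37
                    paired = [(i + t, j0 + s - 1 - t) for t in range(s)]
                    out.append(DuplexStructure(offset=loop, paired=paired,
                                               result=_make_result(dh, ds, None)))
    out.sort(key=lambda st: st.result.dG37)
    return out


def oligo_hairpin(
    seq: str,
    table: NNTable | None = None,
    min_stem: int = 2,
    top_n: int = 5,
) -> list[DuplexStructure]:
    """Fold-back (hairpin) structures of a single oligo, most stable first.

    The 5' side is annealed against the 3' side over all register shifts;
    every fully complementary stem with a loop of at least 3 nt is scored as
    nearest-neighbor stem stacking plus the loop initiation penalty.
    """
    table = table or default_table("DNA")
    seq = _norm_seq(seq, table)
    if len(seq) < 8:
        raise ValueError("hairpin analysis needs at least 8 nt")
    return _hairpin_structures(seq, table, min_stem=min_stem)[:top_n]


def scan_hairpins(
    genome,
    window: int = 60,
    min_stem: int = 4,
    max_loop: int = 30,
    dg_threshold: float = -5.0,
    table: NNTable | None = None,
    both_strands: bool = True,
) -> list[HairpinCandidate]:
    """Genome-wide hairpin scan with RNA thermodynamics.

    Every inverted repeat with stem ≥ ``min_stem``, loop in [3, ``max_loop``]
    and total span ≤ ``window`` is scored as an RNA hairpin; candidates with
    ΔG37 ≤ ``dg_threshold`` are reported, overlapping candidates deduplicated
    keeping the most stable.  Positions are forward-strand 0-based starts of
    the full hairpin span.
    """
    table = table or default_table("RNA")
    seq = (genome.seq if isinstance(genome, GenomeSequence) else str(genome)).upper()
    if window < 2 * min_stem + 3:
        raise ValueError("window must be >= 2*min_stem + 3")
    cands: list[HairpinCandidate] = []
    for strand in ("+", "-") if both_strands else ("+",):
        s_fwd = seq if strand == "+" else reverse_complement(seq)
        rna = s_fwd.replace("T", "U")
        a = np.frombuffer(rna.encode(), dtype=np.uint8)
        comp = np.zeros(256, dtype=np.uint8)
        for x, y in zip(b"ACGU", b"UGCA"):
            comp[x] = y
        ac = comp[a]
        L = len(a)
        max_stem = (window - 3) // 2
        for stem in range(min_stem, max_stem + 1):
            for loop in range(3, max_loop + 1):
                span = 2 * stem + loop
                if span > window or span > L:
                    continue
                n_pos = L - span + 1
                m = np.ones(n_pos, dtype=bool)
                for t in range(stem):
                    m &= a[t : t + n_pos] == ac[span - 1 - t : span - 1 - t + n_pos]
                for p in np.flatnonzero(m):
                    p = int(p)
                    stem_seq = rna[p : p + stem]
                    dh, ds = _stack_sum(stem_seq, table)
                    ds += -table.loop_penalty(loop) * 1000.0 / T37
                    dg = dh - T37 * ds / 1000.0
                    if dg <= dg_threshold:
                        pos = p if strand == "+" else L - (p + span)
                        cands.append(HairpinCandidate(pos=pos, stem_len=stem,
                                                      loop_len=loop, dG=dg, strand=strand))
    # dedup overlapping spans, keep most stable
    cands.sort(key=lambda h: h.dG)
    kept: list[HairpinCandidate] = []
    for h in cands:
        span_h = (h.pos, h.pos + 2 * h.stem_len + h.loop_len)
        if any(span_h[0] < k.pos + 2 * k.stem_len + k.loop_len and k.pos < span_h[1] for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.pos)
    return kept
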