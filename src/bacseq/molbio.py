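"""Molecular-biology design utilities: PCR primer design, on-sequence oligo
design, OD-to-concentration conversion (Beer-Lambert approximation with
per-base extinction coefficients) and codon-usage-driven re-encoding of
proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .genome_io import GenomeSequence, reverse_complement, translate_cds
from .seq_tools import codon_to_aa
from .thermo import (
    DEFAULT_CONC,
    NNTable,
    default_table,
    duplex_thermo,
    oligo_dimers,
    oligo_hairpin,
)

log = logging.getLogger(__name__)

# per-base extinction coefficients at 260 nm, L/(mol*cm)
EXTINCTION = {"A": 15200, "G": 12010, "C": 7050, "T": 8400}


@dataclass
class Oligo:
    seq: str
    tm: float
    dg_hairpin: float = 0.0  # 0 when no fold-back structure exists
    dg_dimer: float = 0.0  # self-dimer; 0 when no structure exists
    mod5: str | None = None
    mod3: str | None = None


@dataclass
class PrimerConstraints:
    tm_range: tuple[float, float] = (55.0, 65.0)
    len_range: tuple[int, int] = (18, 25)
    amplicon_range: tuple[int, int] = (80, 400)
    gc_range: tuple[float, float] = (0.3, 0.7)
    max_hairpin_dg: float = -3.0  # reject structures MORE stable (dG below) this
    max_dimer_dg: float = -6.0
    no_3prime_runs: bool = False  # optional: reject >3 identical 3'-end bases


@dataclass
class ExtinctionInput:
    nA: int
    nG: int
    nC: int
    nT: int
    M: float = 0.0
    od: float = 0.0


def make_oligo(seq: str, table: NNTable | None = None, conc: float = DEFAULT_CONC,
               mod5: str | None = None, mod3: str | None = None) -> Oligo:
    table = table or default_table("DNA")
    tm = duplex_thermo(seq, table, oligo_conc=conc).tm
    try:
        hp = oligo_hairpin(seq, table, top_n=1)
    except ValueError:
        hp = []
    dimers = oligo_dimers(seq, seq, table, top_n=1)
    return Oligo(
        seq=seq,
        tm=tm,
        dg_hairpin=hp[0].result.dG37 if hp else 0.0,
        dg_dimer=dimers[0].result.dG37 if dimers else 0.0,
        mod5=mod5,
        mod3=mod3,
    )


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _passes(o: Oligo, c: PrimerConstraints, rejects: dict[str, int]) -> bool:
    ok = True
    if not c.tm_range[0] <= o.tm <= c.tm_range[1]:
        rejects["tm"] += 1
        ok = False
    if not c.gc_range[0] <= _gc_fraction(o.seq) <= c.gc_range[1]:
        rejects["gc"] += 1
        ok = False
    if o.dg_hairpin < c.max_hairpin_dg:
        rejects["hairpin"] += 1
        ok = False
    if o.dg_dimer < c.max_dimer_dg:
        rejects["dimer"] += 1
        ok = False
    if c.no_3prime_runs and len(o.seq) >= 4 and len(set(o.seq[-4:])) == 1:
        rejects["3prime_run"] += 1
        ok = False
    return ok


def design_primers(
    target: str,
    constraints: PrimerConstraints | None = None,
    table: NNTable | None = None,
    conc: float = DEFAULT_CONC,
    max_pairs: int = 20,
) -> tuple[list[tuple[Oligo, Oligo, int]], dict[str, int]]:
    """Design ranked forward/reverse primer pairs for a target sequence.

    All subsequences in the length range are enumerated as candidates,
    filtered individually on Tm, GC and secondary-structure stability, then
    paired subject to the amplicon-length range.  Pairs are ranked by Tm
    balance (|Tm_f − Tm_r|) and then by least stable secondary structure.
    Returns the ranked pairs and per-filter rejection counts (useful when
    the result is empty).
    """
    c = constraints or PrimerConstraints()
    table = table or default_table("DNA")
    target = target.upper()
    L = len(target)
    if L < c.amplicon_range[0]:
        raise ValueError(f"target ({L} nt) shorter than minimum amplicon {c.amplicon_range[0]}")
    rejects = {"tm": 0, "gc": 0, "hairpin": 0, "dimer": 0, "3prime_run": 0}
    fwd: list[tuple[int, Oligo]] = []  # (start, oligo)
    rev: list[tuple[int, Oligo]] = []  # (end on target, oligo)
    for length in range(c.len_range[0], c.len_range[1] + 1):
        for start in range(0, L - length + 1):
            sub = target[start : start + length]
            o = make_oligo(sub, table, conc)
            if _passes(o, c, rejects):
                fwd.append((start, o))
            ro = make_oligo(reverse_complement(sub), table, conc)
            if _passes(ro, c, rejects):
                rev.append((start + length, ro))
    pairs: list[tuple[float, float, Oligo, Oligo, int]] = []
    for fs, fo in fwd:
        for re_, ro in rev:
            amplicon = re_ - fs
            if not c.amplicon_range[0] <= amplicon <= c.amplicon_range[1]:
                continue
            dtm = abs(fo.tm - ro.tm)
            worst_dg = min(fo.dg_hairpin, fo.dg_dimer, ro.dg_hairpin, ro.dg_dimer)
            pairs.append((dtm, -worst_dg, fo, ro, amplicon))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return [(fo, ro, amp) for _dtm, _dg, fo, ro, amp in pairs[:max_pairs]], rejects


def oligo_at(
    genome,
    start: int,
    end: int,
    strand: str = "+",
    table: NNTable | None = None,
    conc: float = DEFAULT_CONC,
) -> Oligo:
    """Oligo over a genome window, with Tm/hairpin/self-dimer populated."""
    seq = genome.seq if isinstance(genome, GenomeSequence) else str(genome).upper()
    if not 0 <= start < end <= len(seq):
        raise ValueError(f"window [{start}, {end}) outside sequence of length {len(seq)}")
    if end - start > 200:
        raise ValueError("oligo windows are limited to 200 nt")
    sub = seq[start:end]
    if strand == "-":
        sub = reverse_complement(sub)
    return make_oligo(sub, table, conc)


# --- OD to concentration ------------------------------------------------------


def load_modifications(path=None) -> dict[str, float]:
    """Modification-name -> extinction contribution table (editable TSV)."""
    if path is None:
        text = resources.files("bacseq").joinpath("data").joinpath("modifications.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mods = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, eps = line.split("\t")[:2]
        mods[name] = float(eps)
    return mods


def extinction_input(seq: str, od: float, mod5: str | None = None, mod3: str | None = None,
                     mods: dict[str, float] | None = None) -> ExtinctionInput:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError("oligo sequence must be ACGT")
    mods = mods if mods is not None else load_modifications()
    m = 0.0
    for mod in (mod5, mod3):
        if mod is not None:
            if mod not in mods:
                raise ValueError(f"unknown modification {mod!r}; known: {sorted(mods)}")
            m += mods[mod]
    return ExtinctionInput(nA=seq.count("A"), nG=seq.count("G"), nC=seq.count("C"),
                           nT=seq.count("T"), M=m, od=od)


def od_to_concentration(x: ExtinctionInput) -> float:
    """Oligo concentration (mol/L) from absorbance at 260 nm.

    c = OD / (nA·15200 + nG·12010 + nC·7050 + nT·8400 + M), the base-
    composition approximation of the Beer-Lambert law for a 1 cm path.
    """
    eps = (
        x.nA * EXTINCTION["A"]
        + x.nG * EXTINCTION["G"]
        + x.nC * EXTINCTION["C"]
        + x.nT * EXTINCTION["T"]
        + x.M
    )
    if eps <= 0:
        raise ValueError("total extinction coefficient is zero")
    return x.od / eps


def od_to_micromolar(x: ExtinctionInput) -> float:
    return od_to_concentration(x) * 1e6


def dilution_volume(stock_molar: float, target_molar: float, final_volume: float) -> float:
    """Volume of stock needed to prepare ``final_volume`` at ``target_molar``."""
    if stock_molar <= 0:
        raise ValueError("stock concentration must be positive")
    if target_molar > stock_molar:
        raise ValueError("target concentration exceeds stock")
    return final_volume * target_molar / stock_molar


# --- codon optimization -------------------------------------------------------


def usage_from_table(df: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Convert a codon-usage DataFrame (codon, aa, fraction) to aa -> codon map."""
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["aa"], {})[row["codon"]] = float(row["fraction"])
    return out


def optimize_codons(
    protein: str,
    usage,
    mode: str = "max_frequency",
) -> str:
    """Re-encode a protein using the given codon-usage table.

    ``max_frequency`` picks each residue's most frequent codon (ties broken
    alphabetically).  ``usage`` is either the DataFrame from
    :func:`bacseq.seq_tools.codon_usage` or an aa -> {codon: fraction} dict.
    The result always translates back to the input protein.
    """
    if mode != "max_frequency":
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(usage, pd.DataFrame):
        usage = usage_from_table(usage)
    protein = protein.upper().strip("*") + ""
    dna = []
    for res in protein:
        if res not in usage or not usage[res]:
            raise ValueError(f"residue {res!r} missing from codon-usage table")
        codons = usage[res]
        best = sorted(codons.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if codon_to_aa(best) != res:
            raise ValueError(f"table assigns codon {best} to {res!r} but it encodes {codon_to_aa(best)!r}")
        dna.append(best)
    result = "".join(dna)
    if translate_cds(result + "TAA") != protein:
        raise AssertionError("round-trip translation failed")
    return result
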