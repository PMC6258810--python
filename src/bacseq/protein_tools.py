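"""Protein charge, isoelectric point, molecular weight and the theoretical
2D-electrophoresis map of a genome's proteome.

The net charge at a given pH sums Henderson-Hasselbalch occupancies over the
ionizable groups (termini plus D, E, C, Y, H, K, R side chains); the
isoelectric point is found by bisection, which is valid because the net
charge is strictly decreasing in pH.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

from .genome_io import Annotation, GenomeSequence, feature_sequence, translate_cds

log = logging.getLogger(__name__)

BASIC_GROUPS = ("K", "R", "H")
ACIDIC_GROUPS = ("D", "E", "C", "Y")
AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PKTable:
    pk: dict[str, float]

    def __post_init__(self) -> None:
        required = {"Nterm", "Cterm", *BASIC_GROUPS, *ACIDIC_GROUPS}
        missing = required - set(self.pk)
        if missing:
            raise ValueError(f"pK table missing groups: {sorted(missing)}")
        bad = {g: v for g, v in self.pk.items() if not 0 < v < 14}
        if bad:
            raise ValueError(f"pK values out of (0, 14): {bad}")


@dataclass
class ProteinPoint:
    id: str
    pi: float
    mw: float


def load_pk_table(path=None) -> PKTable:
    if path is None:
        text = resources.files("bacseq").joinpath("data").joinpath("pk_table.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    pk = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        group, value = line.split("\t")[:2]
        pk[group] = float(value)
    return PKTable(pk=pk)


_DEFAULT_PK: PKTable | None = None


def default_pk_table() -> PKTable:
    global _DEFAULT_PK
    if _DEFAULT_PK is None:
        _DEFAULT_PK = load_pk_table()
    return _DEFAULT_PK


def _check_protein(protein: str) -> str:
    protein = protein.upper().rstrip("*")
    bad = set(protein) - AA20
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    if not protein:
        raise ValueError("empty protein")
    return protein


def net_charge(protein: str, ph: float, table: PKTable | None = None) -> float:
    """Net charge at a pH: positive groups minus negative groups.

    Q(pH) = Σ_basic 1/(1+10^(pH−pK)) − Σ_acidic 1/(1+10^(pK−pH)); the free
    termini contribute once each.
    """
    protein = _check_protein(protein)
    pk = (table or default_pk_table()).pk
    q = 1.0 / (1.0 + 10.0 ** (ph - pk["Nterm"]))
    q -= 1.0 / (1.0 + 10.0 ** (pk["Cterm"] - ph))
    for g in BASIC_GROUPS:
        n = protein.count(g)
        if n:
            q += n / (1.0 + 10.0 ** (ph - pk[g]))
    for g in ACIDIC_GROUPS:
        n = protein.count(g)
        if n:
            q -= n / (1.0 + 10.0 ** (pk[g] - ph))
    return q


def isoelectric_point(protein: str, table: PKTable | None = None, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14] to |Q| < tol."""
    protein = _check_protein(protein)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(protein, mid, table)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_mw(protein: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    protein = _check_protein(protein)
    return float(_bio_mw(protein, seq_type="protein"))


def proteome_2d_map(
    annotation: Annotation,
    genome: GenomeSequence,
    table: PKTable | None = None,
) -> pd.DataFrame:
    """Theoretical 2D-gel coordinates (pI, MW) for every CDS in a genome.

    Untranslatable CDSs (internal stops, ambiguous bases) are skipped with a
    warning.  Returns a DataFrame with columns id, pi, mw.
    """
    points: list[ProteinPoint] = []
    for f in annotation.by_type("CDS"):
        try:
            prot = translate_cds(feature_sequence(f, genome))
            prot = _check_protein(prot)
            if "*" in prot:
                raise ValueError("internal stop codon")
            points.append(ProteinPoint(id=f.id, pi=isoelectric_point(prot, table), mw=protein_mw(prot)))
        except ValueError as exc:
            warnings.warn(f"skipping CDS {f.id!r}: {exc}")
    return pd.DataFrame(
        {"id": [p.id for p in points], "pi": [p.pi for p in points], "mw": [p.mw for p in points]}
    )
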