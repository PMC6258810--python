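"""Genome and annotation I/O with a uniform feature model.

Sequences come in as FASTA or GenBank (via Biopython), annotations as GenBank
features or GFF3.  All coordinates inside the package are 0-based half-open;
conversion to/from the 1-based inclusive conventions of GenBank and GFF3
happens only in the parsers and writers in this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_FTYPES = {"CDS", "gene", "rRNA", "tRNA", "TU", "TSS", "terminator", "misc"}

_STRICT_ALPHABET = set("ACGTN")
_IUPAC_ALPHABET = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A single replicon: id, uppercase sequence, circular flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A genomic feature in 0-based half-open coordinates.

    ``parts`` holds explicit sub-locations for compound (join) features, e.g.
    a CDS wrapping the origin of a circular genome; ``start``/``end`` then
    bound the first and last part respectively.
    """

    id: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: dict[str, str] = field(default_factory=dict)
    parts: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.parts is None and not 0 <= self.start < self.end:
            raise ValueError(f"feature {self.id!r}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        if self.parts:
            return sum(e - s for s, e in self.parts)
        return self.end - self.start


@dataclass
class Annotation:
    """Ordered feature list for one genome; features kept sorted by start."""

    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))

    def add(self, feature: Feature) -> None:
        self.features.append(feature)
        self.sort()

    def by_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


def _check_alphabet(seq: str, seq_id: str, allow_iupac: bool) -> None:
    allowed = _IUPAC_ALPHABET if allow_iupac else _STRICT_ALPHABET
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains non-{'IUPAC' if allow_iupac else 'ACGTN'} "
            f"symbols: {sorted(bad)}"
            + ("" if allow_iupac else " (pass allow_iupac=True to accept ambiguity codes)")
        )


def _ftype_of(gb_type: str) -> str:
    return gb_type if gb_type in VALID_FTYPES else "misc"


def _features_from_seqrecord(record) -> Annotation:
    ann = Annotation(genome_id=record.id)
    seen: dict[str, int] = {}
    for i, f in enumerate(record.features):
        if f.type == "source":
            continue
        quals = {k: "; ".join(map(str, v)) for k, v in f.qualifiers.items()}
        fid = quals.get("locus_tag") or quals.get("gene") or f"{f.type}_{i}"
        if fid in seen:
            seen[fid] += 1
            fid = f"{fid}.{seen[fid]}"
        else:
            seen[fid] = 0
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted((int(p.start), int(p.end)) for p in f.location.parts)
        feat = Feature(
            id=fid,
            ftype=_ftype_of(f.type),
            start=parts[0][0],
            end=parts[-1][1],
            strand=strand,
            qualifiers=quals,
            parts=parts if len(parts) > 1 else None,
        )
        ann.features.append(feat)
    ann.sort()
    return ann


def read_genome(
    path, fmt: str = "fasta", allow_iupac: bool = False
) -> tuple[list[GenomeSequence], dict[str, Annotation]]:
    """Read genomes from FASTA or GenBank.

    Returns the sequences in file order and a dict of per-genome annotations
    (empty for FASTA).  GenBank 1-based inclusive locations are converted to
    0-based half-open; ``join`` locations become multi-part features.
    """
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {fmt!r}: use 'fasta' or 'genbank'")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no {fmt} records found (empty or malformed file)")
    genomes: list[GenomeSequence] = []
    annotations: dict[str, Annotation] = {}
    for rec in records:
        seq = str(rec.seq)
        _check_alphabet(seq, rec.id, allow_iupac)
        circular = "circular" in str(rec.annotations.get("topology", "")).lower()
        genomes.append(GenomeSequence(id=rec.id, seq=seq, circular=circular))
        if fmt == "genbank":
            annotations[rec.id] = _features_from_seqrecord(rec)
    return genomes, annotations


def write_fasta(genomes: list[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


_GFF_COLS = 9


def read_gff(path, annotation: Annotation, known_ids: set[str] | None = None) -> Annotation:
    """Append GFF3 features to ``annotation`` (in place) and return it.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Strand ``.`` is stored as ``+`` with an ``unstranded`` qualifier so it can
    be excluded from stranded analyses downstream.
    """
    known = known_ids if known_ids is not None else {annotation.genome_id}
    seen = {f.id for f in annotation.features}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if seqid not in known:
                raise ValueError(
                    f"{path}:{lineno}: unknown seqid {seqid!r}; known genomes: {sorted(known)}"
                )
            qualifiers: dict[str, str] = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    qualifiers[k.strip()] = v.strip()
            fid = qualifiers.get("ID") or f"{ftype}_{lineno}"
            if fid in seen:
                fid = f"{fid}.{lineno}"
            seen.add(fid)
            if strand == ".":
                qualifiers["unstranded"] = "true"
                strand = "+"
            annotation.features.append(
                Feature(
                    id=fid,
                    ftype=_ftype_of(ftype),
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    qualifiers=qualifiers,
                )
            )
    annotation.sort()
    return annotation


def write_gff(annotation: Annotation, path, source: str = "bacseq") -> None:
    """Write an Annotation as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            strand = "." if f.qualifiers.get("unstranded") == "true" else f.strand
            attrs = [f"ID={f.id}"] + [
                f"{k}={v}" for k, v in f.qualifiers.items() if k not in ("ID", "unstranded")
            ]
            fh.write(
                "\t".join(
                    [
                        annotation.genome_id,
                        source,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def feature_sequence(feature: Feature, genome: GenomeSequence) -> str:
    """Nucleotide sequence of a feature, reverse-complemented on the minus strand."""
    parts = feature.parts or [(feature.start, feature.end)]
    seq = "".join(genome.seq[s:e] for s, e in parts)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate_cds(seq: str, table: int = 11) -> str:
    """Translate a CDS with the bacterial code; trailing stop removed.

    Lengths not divisible by 3 are truncated to whole codons with a warning.
    """
    if len(seq) % 3:
        warnings.warn(f"CDS length {len(seq)} not divisible by 3; truncating to whole codons")
        seq = seq[: 3 * (len(seq) // 3)]
    prot = str(Seq(seq).translate(table=table))
    return prot[:-1] if prot.endswith("*") else prot


def extract_sequences(
    annotation: Annotation,
    genome: GenomeSequence,
    ftype: str = "CDS",
    as_protein: bool = False,
) -> list[tuple[str, str]]:
    """Extract (id, sequence) for all features of a type; optional translation."""
    out: list[tuple[str, str]] = []
    for f in annotation.by_type(ftype):
        seq = feature_sequence(f, genome)
        out.append((f.id, translate_cds(seq) if as_protein else seq))
    return out
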