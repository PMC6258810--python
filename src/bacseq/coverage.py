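"""Per-base read-coverage tracks: construction from SAM/BAM, native text I/O,
normalization and per-feature expression (FPKM).

Two coverage representations are supported.  ``full_read`` increments every
reference position a read aligns to (the usual pileup picture); for 5'-end
enriched libraries ``first_nucleotide`` increments only the 5'-most aligned
base of each read, which resolves transcription start sites at single-base
precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome_io import Annotation, GenomeSequence

log = logging.getLogger(__name__)

MODES = ("full_read", "first_nucleotide")


@dataclass
class CoverageTrack:
    """Coverage values over one genome, one strand, one representation."""

    genome_id: str
    strand: str  # '+', '-' or 'both'
    mode: str  # 'full_read' or 'first_nucleotide'
    values: np.ndarray
    library_size: int = 0
    mean_read_length: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"strand must be '+', '-' or 'both', got {self.strand!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def copy_with(self, values: np.ndarray) -> "CoverageTrack":
        return CoverageTrack(
            genome_id=self.genome_id,
            strand=self.strand,
            mode=self.mode,
            values=values,
            library_size=self.library_size,
            mean_read_length=self.mean_read_length,
            name=self.name,
        )


@dataclass
class FeatureExpression:
    feature_id: str
    count: float
    fpkm: float
    length: int
    count_units: str = "reads"  # 'reads' when a mean read length is known, else 'bases'


def _read_5prime_position(read: pysam.AlignedSegment) -> int:
    """Reference position of the read's 5'-most base (rightmost for reverse reads)."""
    if read.is_reverse:
        return read.reference_end - 1
    return read.reference_start


def coverage_from_alignments(
    alignments,
    genome: GenomeSequence,
    mode: str = "full_read",
    stranded: bool = False,
) -> dict[str, CoverageTrack]:
    """Build coverage track(s) from a SAM/BAM file or open AlignmentFile.

    Unmapped, secondary and supplementary records are skipped, so each
    multi-mapping read contributes once through its primary alignment.
    Deletions and soft clips receive no coverage.  Returns a dict keyed by
    strand: ``{'both': track}`` or ``{'+': ..., '-': ...}``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    own = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        L = len(genome.seq)
        if genome.id in alignments.references:
            ref_len = alignments.get_reference_length(genome.id)
            if ref_len != L:
                raise ValueError(
                    f"reference {genome.id!r} length {ref_len} in alignment header "
                    f"differs from genome length {L}"
                )
        strands = ("+", "-") if stranded else ("both",)
        cov = {s: np.zeros(L) for s in strands}
        n_used = {s: 0 for s in strands}
        read_len_sum = 0.0
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != genome.id:
                continue
            s = ("-" if read.is_reverse else "+") if stranded else "both"
            if mode == "full_read":
                pos = read.get_reference_positions()
                np.add.at(cov[s], pos, 1)
            else:
                cov[s][_read_5prime_position(read)] += 1
            n_used[s] += 1
            read_len_sum += read.query_alignment_length or read.query_length or 0
        total = sum(n_used.values())
        if total == 0:
            warnings.warn("no usable reads; returning empty coverage track(s)")
        mean_rl = read_len_sum / total if total else None
        return {
            s: CoverageTrack(
                genome_id=genome.id,
                strand=s,
                mode=mode,
                values=cov[s],
                library_size=n_used[s],
                mean_read_length=mean_rl,
            )
            for s in strands
        }
    finally:
        if own:
            alignments.close()


# --- native text format -----------------------------------------------------
# Header line:  #genome_id<TAB>strand<TAB>mode<TAB>length
# then one coverage value per line.  The multi-track table variant is a TSV
# with a 0-based `pos` column and one column per track named
# "<sample>|<strand>|<mode>".


def write_native(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{track.genome_id}\t{track.strand}\t{track.mode}\t{len(track)}\n")
        fh.write("\n".join(format(v, "g") for v in track.values))
        fh.write("\n")


def read_native(path) -> CoverageTrack:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#' header line")
        fields = header[1:].split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}: header must have 4 tab-separated fields")
        genome_id, strand, mode, length = fields[0], fields[1], fields[2], int(fields[3])
        values = np.empty(length)
        n = 0
        for lineno, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            if n >= length:
                raise ValueError(f"{path}: more values than header length {length}")
            try:
                values[n] = float(line)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coverage value {line!r}") from None
            n += 1
        if n != length:
            raise ValueError(f"{path}: header declares {length} values but body has {n}")
    return CoverageTrack(genome_id=genome_id, strand=strand, mode=mode, values=values)


def write_table(tracks: list[CoverageTrack], path) -> None:
    """Bundle several tracks of equal length into one TSV table."""
    if not tracks:
        raise ValueError("no tracks to write")
    L = len(tracks[0])
    if any(len(t) != L for t in tracks):
        raise ValueError("all tracks in a table must have the same length")
    data = {"pos": np.arange(L)}
    for t in tracks:
        name = t.name or t.genome_id
        data[f"{name}|{t.strand}|{t.mode}"] = t.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_table(path, genome_id: str | None = None) -> list[CoverageTrack]:
    df = pd.read_csv(path, sep="\t")
    if "pos" not in df.columns:
        raise ValueError(f"{path}: table format requires a 'pos' column")
    tracks = []
    for col in df.columns:
        if col == "pos":
            continue
        parts = col.split("|")
        if len(parts) != 3:
            raise ValueError(f"{path}: column {col!r} is not of the form sample|strand|mode")
        name, strand, mode = parts
        tracks.append(
            CoverageTrack(
                genome_id=genome_id or name,
                strand=strand,
                mode=mode,
                values=df[col].to_numpy(dtype=float),
                name=name,
            )
        )
    return tracks


# --- normalization and expression -------------------------------------------


def _cds_mask(annotation: Annotation, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    cds = annotation.by_type("CDS")
    if not cds:
        raise ValueError("CDS normalization requested but annotation has no CDS features")
    for f in cds:
        for s, e in f.parts or [(f.start, f.end)]:
            mask[s:e] = True
    return mask


def normalize(
    track: CoverageTrack,
    method: str = "total",
    annotation: Annotation | None = None,
    log2: bool = False,
) -> CoverageTrack:
    """Scale coverage to per-million units of total or CDS-restricted coverage.

    ``cds`` restricts the normalizer to positions inside annotated CDSs, which
    keeps heavily overrepresented features (rRNA, tRNA operons) from deflating
    everything else.  ``log2`` applies log2(x+1) after scaling.
    """
    if method == "total":
        normalizer = float(track.values.sum())
    elif method == "cds":
        if annotation is None:
            raise ValueError("method='cds' requires an annotation")
        normalizer = float(track.values[_cds_mask(annotation, len(track))].sum())
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if normalizer <= 0:
        raise ValueError(f"zero normalizer for method {method!r}: cannot normalize")
    values = track.values * (1e6 / normalizer)
    if log2:
        values = np.log2(values + 1.0)
    return track.copy_with(values)


def feature_expression(
    track: CoverageTrack,
    annotation: Annotation,
    method: str = "total",
    mean_read_length: float | None = None,
) -> list[FeatureExpression]:
    """Per-feature counts and FPKM.

    The count is the base-coverage sum over the feature divided by the mean
    read length when one is known (read-count units), otherwise the raw base
    sum (flagged via ``count_units='bases'``).  FPKM = count * 1e9 /
    (length * normalizer) with the normalizer computed over the whole genome
    (``total``) or CDS positions only (``cds``), in the same units.
    """
    if not annotation.features:
        raise ValueError("empty annotation")
    L = len(track)
    rl = mean_read_length if mean_read_length is not None else track.mean_read_length
    units = "reads" if rl else "bases"
    scale = rl if rl else 1.0
    if method == "total":
        normalizer = float(track.values.sum()) / scale
    elif method == "cds":
        normalizer = float(track.values[_cds_mask(annotation, L)].sum()) / scale
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if normalizer <= 0:
        raise ValueError("zero normalizer")
    out = []
    for f in annotation.features:
        if f.end > L or f.start < 0:
            raise ValueError(f"feature {f.id!r} [{f.start}, {f.end}) outside genome of length {L}")
        base_sum = sum(float(track.values[s:e].sum()) for s, e in (f.parts or [(f.start, f.end)]))
        count = base_sum / scale
        length = len(f)
        out.append(
            FeatureExpression(
                feature_id=f.id,
                count=count,
                fpkm=count * 1e9 / (length * normalizer),
                length=length,
                count_units=units,
            )
        )
    return out


def expression_table(expr: list[FeatureExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [e.feature_id for e in expr],
            "length": [e.length for e in expr],
            "count": [e.count for e in expr],
            "count_units": [e.count_units for e in expr],
            "fpkm": [e.fpkm for e in expr],
        }
    )
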