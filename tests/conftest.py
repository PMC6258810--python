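"""Shared fixtures: small synthetic genome/annotation/alignment inputs,
generated programmatically at test time."""

import numpy as np
import pytest

from bacseq.genome_io import Annotation, Feature, GenomeSequence

# 30 nt circular synthetic genome with an origin-wrapping join CDS
GENBANK_TEXT = """\
LOCUS       testgb                    30 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  synthetic 30 nt test genome.
ACCESSION   testgb
VERSION     testgb
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     source          1..30
     CDS             join(25..30,1..6)
                     /locus_tag="wrap1"
     gene            7..15
                     /locus_tag="g2"
ORIGIN
        1 atggccaaat aggggtttcc catgaaatga
//
"""


@pytest.fixture
def genbank_file(tmp_path):
    p = tmp_path / "test.gb"
    p.write_text(GENBANK_TEXT)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def small_genome(rng):
    return GenomeSequence(id="chr1", seq=random_dna(rng, 400))


def make_sam(reads, ref="chr1", ref_len=400):
    """Build SAM text from (name, flag, pos0, cigar, seq) tuples."""
    lines = [f"@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{ref}\tLN:{ref_len}"]
    for name, flag, pos0, cigar, seq in sorted(reads, key=lambda r: r[2]):
        lines.append(
            f"{name}\t{flag}\t{ref}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{'I' * len(seq)}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def sam_file(tmp_path, small_genome, rng):
    """~100 random single-end reads, mostly pure matches plus clipped/indel ones."""
    L = len(small_genome.seq)
    reads = []
    for i in range(100):
        rl = int(rng.integers(20, 51))
        pos = int(rng.integers(0, L - rl - 5))
        flag = 16 if rng.random() < 0.5 else 0
        r = rng.random()
        if r < 0.7:
            cigar, seq_len = f"{rl}M", rl
        elif r < 0.8:
            cigar, seq_len = f"5S{rl}M", rl + 5
        elif r < 0.9:
            cigar, seq_len = f"{rl // 2}M2D{rl - rl // 2}M", rl
        else:
            cigar, seq_len = f"{rl // 2}M3I{rl - rl // 2}M", rl + 3
        reads.append((f"r{i}", flag, pos, cigar, "A" * seq_len))
    p = tmp_path / "reads.sam"
    p.write_text(make_sam(reads, ref_len=L))
    return p


@pytest.fixture
def two_gene_annotation():
    """Two CDSs plus one rRNA, for normalization tests."""
    ann = Annotation(genome_id="chr1")
    ann.features = [
        Feature(id="cdsA", ftype="CDS", start=10, end=110, strand="+"),
        Feature(id="cdsB", ftype="CDS", start=150, end=250, strand="+"),
        Feature(id="rrn", ftype="rRNA", start=300, end=380, strand="+"),
    ]
    ann.sort()
    return ann
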