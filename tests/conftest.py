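import numpy as np
import pytest

from bsrscan import BaseDepths, LocusTable, SnpLocus
from bsrscan.containers import POOLS


def make_locus(unigene="u1", pos=1, t01=(10, 0, 0, 0), t02=(10, 0, 0, 0),
               t03=(10, 0, 0, 0), t04=(10, 0, 0, 0)):
    """Hand-build one SNP locus from per-pool (A, C, G, T) depth tuples."""
    rows = dict(zip(POOLS, (t01, t02, t03, t04)))
    return SnpLocus(unigene, pos, {p: BaseDepths(*rows[p]) for p in POOLS})


def make_table(*loci):
    return LocusTable.from_loci(loci)


@pytest.fixture
def informative_locus():
    """Aa x aa locus: T01 het A/C, T02 hom A, bulks diverged A/C."""
    return make_locus(
        "u1", 10,
        t01=(25, 25, 0, 0), t02=(50, 0, 0, 0),
        t03=(25, 25, 0, 0), t04=(50, 0, 0, 0),
    )


@pytest.fixture
def depth_tsv_factory(tmp_path):
    """Write depth-TSV text (list of data-row strings) and return its path."""
    from bsrscan.io import TSV_HEADER

    def write(rows, header=None, name="depths.tsv", comments=True):
        lines = []
        if comments:
            lines.append("# synthetic fixture")
        lines.append("\t".join(header or TSV_HEADER))
        lines.extend(rows)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return write


VCF_TEMPLATE = """\
##fileformat=VCFv4.2
##contig=<ID={contigs}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


@pytest.fixture
def vcf_factory(tmp_path):
    """Write a small plain-text VCF with AD fields for four samples."""

    def write(records, samples=("s1", "s2", "s3", "s4"), contig="u1", name="calls.vcf"):
        header = VCF_TEMPLATE.format(contigs=contig, samples="\t".join(samples))
        path = tmp_path / name
        path.write_text(header + "\n".join(records) + "\n", encoding="utf-8")
        return path

    return write


def random_depth_vectors(rng, n):
    """(n, 4) random non-degenerate base-depth vectors for property checks."""
    d = rng.integers(0, 60, size=(n, 4))
    d[d.sum(axis=1) == 0, 0] = 1
    return d
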