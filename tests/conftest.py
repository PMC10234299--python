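import pytest

from asmgaps import Thresholds, group_by_contig, simulate_demo
from asmgaps.alignment_io import AlignmentRecord


@pytest.fixture(scope="session")
def t():
    return Thresholds()


@pytest.fixture(scope="session")
def demo():
    """Canonical synthetic diploid: 10-Mbp annotated reference, 12 gaps,
    6 contractions, 6 expansions, 2 inversions, 3 embedded contigs."""
    reference, plan, assembly = simulate_demo(seed=1)
    return reference, plan, assembly


@pytest.fixture(scope="session")
def demo_aset(demo):
    _, _, assembly = demo
    return group_by_contig(assembly.alignments)


def make_record(
    contig="ctg1",
    contig_len=1_000_000,
    qs=0,
    qe=None,
    strand="+",
    chrom="chr1",
    chrom_len=100_000_000,
    ts=0,
    te=None,
    mapq=60,
    sample="s1",
    hap="h1",
):
    """Terse AlignmentRecord builder for unit tests; defaults give a
    full-length forward alignment."""
    if te is None:
        te = ts + (qe - qs if qe is not None else contig_len)
    if qe is None:
        qe = qs + (te - ts)
    return AlignmentRecord(
        query_name=contig, query_len=contig_len, query_start=qs, query_end=qe,
        strand=strand, target_name=chrom, target_len=chrom_len,
        target_start=ts, target_end=te, residue_matches=te - ts,
        block_len=te - ts, mapq=mapq, sample=sample, haplotype=hap,
    )
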