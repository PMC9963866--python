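import numpy as np
import pytest

from isocross import popgen


TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tTET
chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/0:30\t0/1:25\t0/0/0/1:40
chr1\t110\t.\tA\tC,G\t.\tPASS\t.\tGT:DP\t0/0:30\t0/1:25\t0/0:40
chr1\t130\t.\tA\tAT\t.\tPASS\t.\tGT:DP\t0/0:30\t0/1:25\t0/0:40
chr1\t150\t.\tG\tT\t.\tPASS\t.\tGT:AD\t0/1:7,6\t0/0:10,0\t1/1/1/1:20,20
chr1\t160\t.\tG\tT\t.\tPASS\t.\tGT:DP\t./.:0\t0/0:10\t0/0:9
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def make_matrix(calls, pos=None, depth=30, samples=None, chrom="chr1"):
    """GenotypeMatrix from a samples x loci call-code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n)]
    if np.isscalar(depth):
        depth = np.full((n, m), depth, dtype=np.int32)
    return popgen.GenotypeMatrix(
        samples=list(samples),
        chrom=np.asarray([chrom] * m, dtype=object),
        pos=np.asarray(pos),
        ref=np.asarray(["A"] * m, dtype=object),
        alt=np.asarray(["C"] * m, dtype=object),
        calls=calls,
        depth=np.asarray(depth, dtype=np.int32),
    )


@pytest.fixture
def two_clade_matrix():
    """Six samples in two strongly diverged clades of three."""
    rng = np.random.default_rng(7)
    n_loci = 500
    calls = np.zeros((6, n_loci), dtype=np.int8)
    between = rng.choice(n_loci, 120, replace=False)
    calls[3:, between] = 2
    for i in range(6):
        private = rng.choice(n_loci, 15, replace=False)
        calls[i, private] = np.where(calls[i, private] == 2, 0, 2)
    return make_matrix(
        calls,
        pos=np.arange(1, n_loci + 1) * 25,
        samples=["A1", "A2", "A3", "B1", "B2", "B3"],
    )
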