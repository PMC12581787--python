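import numpy as np
import pytest

import panelcraft as pc
from panelcraft.io import GenotypeMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A small structured population shared across read-only tests."""
    cfg = pc.SimConfig(
        n_chrom=2, chrom_length=20_000, n_samples=60, n_snps=300,
        n_subpops=2, fst_target=0.2, seed=11, n_qtn=20,
        missing_rate=0.02, n_duplicate_segments=2,
    )
    genome, dups = pc.simulate_genome(cfg)
    vt, truth = pc.simulate_population(cfg, genome, dups)
    G = vt.to_genotype_matrix()
    y, truth = pc.simulate_phenotype(G, cfg.n_qtn, 0.5, seed=13, truth=truth)
    return {"cfg": cfg, "genome": genome, "dups": dups, "vt": vt,
            "truth": truth, "G": G, "y": y}


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write raw VCF text to a temp file and return its path."""

    def _write(body: str, name: str = "test.vcf"):
        path = tmp_path / name
        path.write_text(body)
        return str(path)

    return _write


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n##contig=<ID=chr2>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


@pytest.fixture
def fixture_vcf(write_vcf_text):
    """Five biallelic SNPs + one triallelic record over three samples."""
    rows = [
        "chr1\t100\t.\tA\tG\t90\tPASS\t.\tGT\t0/0\t0/1\t1/1",
        "chr1\t200\t.\tC\tT\t80\tPASS\t.\tGT\t0|1\t./.\t0/0",
        "chr1\t300\t.\tG\tA,C\t70\tPASS\t.\tGT\t0/1\t0/2\t1/1",  # triallelic
        "chr1\t400\t.\tT\tC\t60\tPASS\t.\tGT\t1/1\t1/1\t0/1",
        "chr2\t150\t.\tA\tC\t50\tPASS\t.\tGT\t0/0\t0/0\t0/1",
        "chr2\t250\t.\tG\tT\t40\tPASS\t.\tGT\t0/1\t1/1\t./.",
    ]
    return write_vcf_text(VCF_HEADER + "\n".join(rows) + "\n")


def make_gm(matrix, sample_prefix="s", snp_prefix="m"):
    matrix = np.asarray(matrix, dtype=np.int8)
    return GenotypeMatrix(
        matrix,
        [f"{sample_prefix}{i}" for i in range(matrix.shape[0])],
        [f"{snp_prefix}{j}" for j in range(matrix.shape[1])],
    )
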