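import numpy as np
import pytest
from hypothesis import settings

from thetanet import CoalescentParams, FuModel, simulate_kingman_sfs

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fu_model_10() -> FuModel:
    return FuModel(10)


@pytest.fixture(scope="session")
def fu_model_40() -> FuModel:
    return FuModel(40)


@pytest.fixture(scope="session")
def kingman_n40_theta40():
    """2e4 Kingman SFS at n=40, theta=40 shared across moment checks."""
    return simulate_kingman_sfs(
        CoalescentParams(40, 40.0), 20_000, rng=np.random.default_rng(2024)
    )


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length={length}>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, records, n_haplotypes=4, length=1000):
    """Write a minimal haploid VCF; records = (pos, ref, alt, info, gts)."""
    samples = "\t".join(f"H{i}" for i in range(1, n_haplotypes + 1))
    lines = [VCF_HEADER.format(length=length, samples=samples).rstrip("\n")]
    for pos, ref, alt, info, gts in records:
        gt_str = "\t".join(str(g) for g in gts)
        lines.append(f"1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\tGT\t{gt_str}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf
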