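import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0|1\t1/1
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|1\t0/1\t0/0
"""

TOY_STRATA = """\
sample_id\tskin_color\tregion
S1\twhite\twest
S2\tadmixed\tcenter
S3\tblack\teast
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_strata(tmp_path):
    p = tmp_path / "strata.tsv"
    p.write_text(TOY_STRATA)
    return p


@pytest.fixture(scope="session")
def cuban_records():
    from pgxfreq import load_cuban_snv_table

    return load_cuban_snv_table()


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding as printed in survey tables (0.225 -> 0.23)."""
    scale = 10**decimals
    return np.floor(x * scale + 0.5) / scale
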