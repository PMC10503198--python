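import numpy as np
import pytest

from flanklift.assembly_io import Assembly, SnpRecord
from flanklift.synthetic_assembly import generate_source, plant_snps


@pytest.fixture(scope="session")
def small_source() -> Assembly:
    """120 kb + 80 kb chromosomes plus one 30 kb unanchored scaffold."""
    return generate_source(
        n_chroms=2,
        chrom_lengths=[120_000, 80_000],
        n_unanchored=1,
        un_lengths=[30_000],
        gc=0.5,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_snps(small_source):
    return plant_snps(small_source, n=80, seed=99)


@pytest.fixture
def toy_assembly() -> Assembly:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return Assembly({"c1": seq})


@pytest.fixture
def snp_factory():
    def make(chrom="c1", pos=100, ref="A", alts=("C",), **kw):
        return SnpRecord(chrom=chrom, pos=pos, ref=ref, alts=list(alts), **kw)

    return make
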