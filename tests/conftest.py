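import numpy as np
import pytest

from strcall.catalog import AlignedRead, ModelParams, RepeatSpec
from strcall.classify import ReferenceFlanks


@pytest.fixture(scope="session")
def model():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_flanks():
    """Fixed random flank sequences shared across classifier tests."""
    rng = np.random.default_rng(7)
    left = "".join(rng.choice(list("ACGT"), 1500))
    right = "".join(rng.choice(list("ACGT"), 1500))
    return ReferenceFlanks(left=left, right=right)


@pytest.fixture(scope="session")
def ggcccc_spec(random_flanks):
    """A GGCCCC locus with 3 reference units, positioned after the left flank."""
    start = len(random_flanks.left)
    return RepeatSpec(
        locus_id="hexamer",
        chrom="chrT",
        start=start,
        end=start + 18,
        motif="GGCCCC",
        pathogenic_cutoff_units=30,
    )


def make_read(name, bases, chrom="chrT", pos=0, mapq=60, qual=30, **kw):
    return AlignedRead(
        name=name,
        bases=bases,
        quals=np.full(len(bases), qual, dtype=np.uint8),
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        **kw,
    )


@pytest.fixture(scope="session")
def read_factory():
    return make_read
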