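import numpy as np
import pytest

from arctos.core import GenotypeMatrix, PopulationMap


def make_gm(genotypes, pos=None, chrom=None, sample_ids=None, **kw) -> GenotypeMatrix:
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    pos = np.arange(1, n_sites + 1) * 10 if pos is None else np.asarray(pos)
    chrom = np.array(["chr1"] * n_sites, dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids=ids, chrom=chrom, pos=pos, genotypes=g, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_popmap():
    return PopulationMap.from_pairs({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """The bundled demo dataset, generated once per test session."""
    from arctos.pipeline import make_demo_dataset

    outdir = tmp_path_factory.mktemp("demo")
    return make_demo_dataset(seed=1, outdir=outdir)
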