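import numpy as np
import pytest

from sweepaxes.io import HaplotypeSet, SnpMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_map(n, chrom="1", spacing=1000, cm_per_mb=1.0, ancestral=None):
    pos = spacing * np.arange(1, n + 1)
    anc = ["A"] * n if ancestral is None else list(ancestral)
    return SnpMap([chrom] * n, pos, pos * cm_per_mb / 1e6,
                  [f"snp{i}" for i in range(n)], anc)


def make_haps(alleles, pops=None, **map_kw):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n, m = alleles.shape
    pops = pops if pops is not None else ["pop"] * n
    return HaplotypeSet(alleles, pops, make_map(m, **map_kw))


@pytest.fixture
def random_haps(rng):
    def _make(n_hap=8, n_snp=12, pops=None, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        alleles = (r.random((n_hap, n_snp)) < r.uniform(0.1, 0.9, n_snp)
                   ).astype(np.uint8)
        return make_haps(alleles, pops)
    return _make
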