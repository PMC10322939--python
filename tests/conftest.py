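import numpy as np
import pytest

from tssgrid.annotation import LandmarkPair
from tssgrid.signal import GenomicSignal


def make_pair(z_U, z_D, strand="+", chrom="chr1", pair_index=1, gene_id="g"):
    return LandmarkPair(gene_id=gene_id, chrom=chrom, strand=strand,
                        z_U=z_U, z_D=z_D, pair_index=pair_index)


@pytest.fixture
def ramp_signal():
    """g(z) = z on a 5 kb chromosome: linear, easy to reason about."""
    return GenomicSignal({"chr1": np.arange(5000, dtype=float)})


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_instance(rng, max_pairs=20, max_len=5000):
    """A random small signal + pair set + rectangle for oracle comparisons."""
    from tssgrid.expansion import RegionSpec

    n = int(rng.integers(300, max_len + 1))
    sig = GenomicSignal({"chr1": rng.random(n) * 10})
    pairs = []
    for k in range(int(rng.integers(1, max_pairs + 1))):
        strand = "+" if rng.random() < 0.5 else "-"
        d = int(rng.integers(1, 150))
        z_U = int(rng.integers(0, n))
        z_D = z_U + d if strand == "+" else z_U - d
        pairs.append(make_pair(z_U, z_D, strand, pair_index=1, gene_id=f"g{k}"))
    x0 = int(rng.integers(-100, 100))
    y0 = int(rng.integers(-200, 100))
    region = RegionSpec(x0, y0, x0 + int(rng.integers(0, 50)), y0 + int(rng.integers(0, 50)))
    return sig, pairs, region
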