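import numpy as np
import pytest

from lincoloc.intervals import GenomicInterval, Track
from lincoloc.simulate import SyntheticConfig


@pytest.fixture
def small_config():
    """A miniature synthetic genome that keeps every stage fast."""
    return SyntheticConfig(
        seed=11,
        n_chroms=2,
        chrom_length=8_000_000,
        n_genes=120,
        n_lincs=500,
        n_contact_genes=60,
        n_noise_contacts=50,
        n_repeat_regions=80,
        n_decoy_contacts=30,
        n_terms=20,
        planted_terms=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


def random_track(rng, n, genome=10_000, max_len=200, name="t"):
    """Small random track on a single tiny chromosome (for brute-force checks)."""
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, genome - 2))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval("chr1", start, min(start + length, genome)))
    return Track(name=name, intervals=ivs)
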