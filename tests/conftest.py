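"""Shared fixtures: random peak sets, small genomes, a session-scoped universe."""

from __future__ import annotations

import numpy as np
import pytest

from broaddomain.core_intervals import Peak, PeakSet
from broaddomain.io_formats import GenomeLayout
from broaddomain.synthetic_data import SyntheticConfig, generate_universe


def random_peaks(
    rng: np.random.Generator,
    n: int,
    chroms: dict[str, int],
    max_len: int = 5000,
    **labels,
) -> PeakSet:
    """n random intervals across the given chromosomes (overlaps allowed)."""
    names = list(chroms)
    peaks = []
    for i in range(n):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(100, max_len))
        start = int(rng.integers(0, chroms[chrom] - length))
        peaks.append(Peak(chrom, start, start + length, name=f"p{i}", **labels))
    return PeakSet(peaks, provenance="random")


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture
def small_genome():
    return GenomeLayout((("chr1", 1_000_000), ("chr2", 800_000), ("chr3", 500_000)))


@pytest.fixture(scope="session")
def default_universe():
    """The default synthetic universe (seed 1); shared, treated read-only."""
    return generate_universe(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down config for fast CLI / end-to-end smoke tests."""
    return SyntheticConfig(
        seed=5,
        n_peaks=2000,
        n_background_genes=100,
        n_other_extras=100,
        n_shared_species=100,
        n_species_only=40,
        network_nodes=200,
        n_planted_hubs=10,
    )
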