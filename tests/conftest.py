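import pathlib

import numpy as np
import pytest

from oncofusion.synthetic import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact study conditions shared by the slower integration tests."""
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=500_000,
        n_genes=100,
        n_peaks_per_factor=200,
        peak_width=200,
        tags_per_library=50_000,
        peak_enrichment=30.0,
        n_samples_per_group=5,
    )


@pytest.fixture(scope="session")
def simulated_dir(small_config, tmp_path_factory) -> pathlib.Path:
    """One full synthetic data set, generated once per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    simulate_all(small_config, outdir)
    return outdir


def random_intervals(rng: np.random.Generator, n: int, chrom_len: int = 100_000,
                     max_width: int = 500, chroms=("chr1",)):
    """Random interval tuples for brute-force comparisons."""
    from oncofusion.intervals import GenomicInterval
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - max_width))
        width = int(rng.integers(1, max_width))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        out.append(GenomicInterval(chrom, start, start + width))
    return out
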