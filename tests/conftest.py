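import numpy as np
import pytest

from mapbench import (
    SamplingConfig,
    SimulationProfile,
    build_artificial_chromosome,
    generate_synthetic_genome,
    sample_regions,
    simulate_reads,
    write_fastq,
)


@pytest.fixture(scope="session")
def toy_genome():
    """100 kb single-contig random genome used across the suite."""
    return generate_synthetic_genome(100_000, n_contigs=1, gc_fraction=0.45, seed=101)


@pytest.fixture(scope="session")
def two_contig_genome():
    return generate_synthetic_genome(80_000, n_contigs=2, gc_fraction=0.5, seed=202)


@pytest.fixture(scope="session")
def toy_sampling_config():
    # 40 kb floor: a scaled-down study size appropriate for a 100 kb fixture
    return SamplingConfig(read_length=100, min_total=40_000, seed=7)


@pytest.fixture(scope="session")
def toy_artificial(toy_genome, toy_sampling_config):
    regions = sample_regions(toy_genome, toy_sampling_config)
    artificial, region_map = build_artificial_chromosome(
        toy_genome, regions, toy_sampling_config
    )
    return regions, artificial, region_map


def make_dataset(genome, *, profile=None, sampling=None, seed=9, out_prefix=None):
    """Sample, build the artificial chromosome, and simulate one read set."""
    sampling = sampling or SamplingConfig(
        read_length=100, min_total=min(40_000, genome.total_length // 2), seed=seed
    )
    profile = profile or SimulationProfile(read_length=100, seed=seed)
    rng = np.random.default_rng(seed)
    regions = sample_regions(genome, sampling, rng)
    artificial, region_map = build_artificial_chromosome(genome, regions, sampling)
    reads, truth = simulate_reads(artificial, region_map, profile, rng)
    paths = None
    if out_prefix is not None:
        paths = write_fastq(reads, out_prefix)
    return regions, artificial, region_map, reads, truth, paths
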