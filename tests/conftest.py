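import numpy as np
import pytest

from epiretina.genome import GeneModel, GenomeAnnotation, ReadLibrary
from epiretina.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Two protein-coding genes on a 100 kb chromosome."""
    genes = [
        GeneModel("gA", "chr1", "+", 10_000, 20_000, [8_000], "protein_coding"),
        GeneModel("gB", "chr1", "-", 40_000, 50_000, [7_000], "protein_coding"),
    ]
    return GenomeAnnotation(genes, {"chr1": 100_000})


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down stated world for fast unit tests (same effect sizes)."""
    return SimConfig(
        n_chroms=1,
        chrom_length=2_000_000,
        n_genes={
            "broad_identity": 6,
            "narrow_housekeeping": 10,
            "other_expressed": 10,
            "silent": 6,
        },
        chip_reads_per_library=40_000,
        erna_mean_reads=120.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def uniform_reads(
    rng: np.random.Generator,
    n: int,
    chrom: str,
    length: int,
    read_length: int = 50,
) -> ReadLibrary:
    """Uniform stranded reads over one chromosome (test helper)."""
    starts = rng.integers(0, length - read_length, size=n).astype(np.int64)
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype("U1")
    return ReadLibrary(
        np.full(n, chrom, dtype=object), starts, starts + read_length, strands
    )
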