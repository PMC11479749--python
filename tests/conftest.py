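import numpy as np
import pytest

from eccv.genome import generate_genome
from eccv.simulate import SimCohortConfig, build_genome


@pytest.fixture(scope="session")
def small_genome():
    """One 200 kb chromosome at human-like GC; shared across tests."""
    return generate_genome({"chr1": 200_000}, base_gc=0.41, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SimCohortConfig(
        n_samples_per_group=2,
        chrom_lengths={"chr1": 200_000, "chr2": 150_000},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort_genome(small_config):
    return build_genome(small_config)


class TextGenome:
    """Tiny literal-sequence genome for hand-computable fixtures."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences
        self.chrom_names = list(sequences)

    @property
    def lengths(self):
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom, start, end):
        from eccv.genome import GenomeError

        seq = self.sequences.get(chrom)
        if seq is None:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= len(seq)):
            raise GenomeError(f"interval {chrom}:{start}-{end} out of bounds")
        return seq[start:end]


@pytest.fixture
def text_genome_factory():
    return TextGenome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
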