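import numpy as np
import pytest

from polterm.annotation import TranscriptModel
from polterm.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic cohort shared by fast integration tests."""
    cfg = SimulationConfig(n_genes=40, length_max=30_000, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_transcript(
    length: int,
    strand: str = "+",
    start: int = 10_000,
    chrom: str = "chr1",
    gene_id: str = "g1",
    transcript_id: str = "t1",
) -> TranscriptModel:
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        span_start=start,
        span_end=start + length,
        exons=[(start, start + length)],
    )
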