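import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tereawaken.annotations import TEAnnotation, TECopy
from tereawaken.intervals import GenomeModel, GenomicInterval

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel(
        {"chr1": 100_000, "chr2": 80_000},
        [GenomicInterval("chr1", 20_000, 25_000), GenomicInterval("chr2", 0, 4_000)],
    )


@pytest.fixture
def toy_te() -> TEAnnotation:
    return TEAnnotation(
        [
            TECopy("a1", "famA", "ERV1", "LTR", GenomicInterval("chr1", 1_000, 1_500, "+")),
            TECopy("a2", "famA", "ERV1", "LTR", GenomicInterval("chr1", 50_000, 50_400, "-")),
            TECopy("b1", "famB", "L1", "LINE", GenomicInterval("chr1", 70_000, 70_900, "+")),
            TECopy("b2", "famB", "L1", "LINE", GenomicInterval("chr2", 10_000, 10_600, "+")),
        ]
    )


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_pos: int = 50_000, max_len: int = 800):
    """Random (chrom, start, end) triples for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append((chrom, start, start + length))
    return out
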