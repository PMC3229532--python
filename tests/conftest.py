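import numpy as np
import pytest

from dupmodes.genome_io import Gene, GenomeAnnotation


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Six genes on two chromosomes with varied exon counts."""
    return GenomeAnnotation(
        [
            Gene("gA", "chr1", 100, 900, "+", 4),
            Gene("gB", "chr1", 5000, 5600, "+", 1),
            Gene("gC", "chr1", 9000, 9600, "-", 2),
            Gene("gD", "chr2", 100, 700, "+", 3),
            Gene("gE", "chr2", 2000, 2600, "-", 1),
            Gene("gF", "chr2", 4000, 4600, "+", 5),
        ],
        {"chr1": 12_000, "chr2": 6_000},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
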