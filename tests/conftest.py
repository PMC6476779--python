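import numpy as np
import pytest

from refugia.coalescent import LocusConfig
from refugia.seq_io import MITOCHONDRIAL, NUCLEAR, Alignment, PopulationAssignment

# the hand-worked toy alignment used throughout: segregating sites at
# (1-based) positions 6 and 10; pair differences (1,2,2,1,1,0)
TOY_SEQS = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAACAAAT", "AAAAACAAAT"]


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_strings(TOY_SEQS, ["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_split(toy_alignment):
    return toy_alignment.take([0, 1]), toy_alignment.take([2, 3])


@pytest.fixture
def small_loci() -> tuple[LocusConfig, LocusConfig]:
    """Short two-locus design for fast simulation tests."""
    return (
        LocusConfig("mtDNA", 300, MITOCHONDRIAL, "mu_mt"),
        LocusConfig("nDNA", 150, NUCLEAR, "mu_nuc"),
    )


@pytest.fixture
def tiny_sizes() -> dict[str, int]:
    return {"Southern": 4, "Northern": 4, "Central": 6}


def random_alignment(
    rng: np.random.Generator,
    n: int | None = None,
    length: int | None = None,
    missing_rate: float = 0.0,
) -> Alignment:
    n = n or int(rng.integers(2, 13))
    length = length or int(rng.integers(5, 51))
    # draw from few ancestral patterns so sites are often polymorphic
    matrix = rng.integers(0, 4, size=(n, length)).astype(np.uint8)
    anchor = rng.integers(0, 4, size=length).astype(np.uint8)
    copy_mask = rng.random((n, length)) < 0.7
    matrix[copy_mask] = np.broadcast_to(anchor, (n, length))[copy_mask]
    if missing_rate > 0:
        miss = rng.random((n, length)) < missing_rate
        matrix[miss] = np.where(rng.random((n, length)) < 0.5, 4, 5).astype(np.uint8)[miss]
    return Alignment(tuple(f"s{i}" for i in range(n)), matrix)
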