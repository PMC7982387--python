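import numpy as np
import pytest

import rhizogeo as rg


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic survey at generator defaults, shared across tests."""
    return rg.simulate_dataset(seed=11)


@pytest.fixture
def toy_alignment():
    """Four 6-bp sequences whose site classes are enumerable by hand."""
    return rg.LocusAlignment(
        "toy", ("s1", "s2", "s3", "s4"), ("ACGTAA", "ACGTAC", "ACGTCC", "ACGACC")
    )


@pytest.fixture
def random_alignment_factory():
    """Small random alignments over ACGT plus optional gap/ambiguity characters."""

    def make(rng: np.random.Generator, n=None, length=None, alphabet="ACGT"):
        n = n if n is not None else int(rng.integers(2, 9))
        length = length if length is not None else int(rng.integers(1, 31))
        chars = np.array(list(alphabet))
        seqs = ["".join(rng.choice(chars, size=length)) for _ in range(n)]
        return rg.LocusAlignment("rand", tuple(f"s{i}" for i in range(n)), tuple(seqs))

    return make


def euclidean_dm(points: np.ndarray, level: str = "trait") -> rg.DistanceMatrix:
    """Distance matrix of row-vector points; labels p0, p1, ..."""
    diff = points[:, None, :] - points[None, :, :]
    vals = np.sqrt((diff ** 2).sum(axis=2))
    return rg.DistanceMatrix([f"p{i}" for i in range(len(points))], vals, level)
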