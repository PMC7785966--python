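import numpy as np
import pytest

import corekit as ck


@pytest.fixture
def toy_genotypes() -> ck.GenotypeMatrix:
    """Four accessions, one locus, three distinct alleles (one heterozygote pattern
    used throughout the hand-computed diversity examples)."""
    calls = np.array(
        [[[150, 150]], [[150, 152]], [[152, 152]], [[150, 154]]], dtype=np.int64
    )
    return ck.GenotypeMatrix(("a1", "a2", "a3", "a4"), ("L1",), calls)


@pytest.fixture
def small_panel() -> ck.GenotypeMatrix:
    """5 accessions x 3 loci with one missing call, for round-trip tests."""
    m = ck.MISSING
    calls = np.array(
        [
            [[150, 152], [200, 200], [301, 305]],
            [[150, 150], [202, 204], [301, 301]],
            [[152, 154], [m, m], [303, 305]],
            [[154, 154], [200, 202], [301, 303]],
            [[150, 152], [204, 204], [305, 305]],
        ],
        dtype=np.int64,
    )
    return ck.GenotypeMatrix(("s1", "s2", "s3", "s4", "s5"), ("L1", "L2", "L3"), calls)


def random_genotypes(rng: np.random.Generator, n: int, loci: int, max_alleles: int = 4,
                     missing_rate: float = 0.1) -> ck.GenotypeMatrix:
    """Small random panel for oracle comparisons."""
    calls = np.empty((n, loci, 2), dtype=np.int64)
    for l in range(loci):
        k = int(rng.integers(1, max_alleles + 1))
        labels = 100 + 2 * np.arange(k)
        calls[:, l, :] = rng.choice(labels, size=(n, 2))
    if missing_rate > 0:
        mask = rng.random((n, loci)) < missing_rate
        for l in range(loci):
            if mask[:, l].all():
                mask[0, l] = False
        calls[mask] = ck.MISSING
    ids = tuple(f"r{i}" for i in range(n))
    loci_ids = tuple(f"L{j}" for j in range(loci))
    return ck.GenotypeMatrix(ids, loci_ids, calls)


@pytest.fixture(scope="session")
def study_like_panel() -> ck.SyntheticPanel:
    """One study-shaped synthetic panel shared across structural tests."""
    return ck.generate(ck.study_like_config(), seed=11)
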