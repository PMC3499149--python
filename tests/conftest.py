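import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from locimpute import (
    MISSING,
    FixtureSpec,
    GenotypeMatrix,
    LocusInfo,
    fallback_map,
    generate_fixture,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_matrix(values, spacing_bp=10_000, chrom="1"):
    """GenotypeMatrix from an n x m array with evenly spaced loci."""
    values = np.asarray(values, dtype=np.int8)
    loci = [
        LocusInfo(f"rs{k}", chrom, (k + 1) * spacing_bp)
        for k in range(values.shape[0])
    ]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return GenotypeMatrix(loci, samples, values)


def random_matrix(rng, n, m, missing_rate=0.1, codes=(0, 1, 2)):
    values = rng.choice(codes, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    values[mask] = MISSING
    return make_matrix(values)


@pytest.fixture
def small_panel():
    """A 6-locus, 4-sample panel with one missing entry, plus its map."""
    values = np.array(
        [
            [0, 0, 2, 1],
            [1, 1, 2, 0],
            [MISSING, 1, 2, 0],
            [2, 2, 0, 1],
            [0, 0, 1, 1],
            [2, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    matrix = make_matrix(values)
    return matrix, fallback_map(matrix.loci)


@pytest.fixture
def ld_fixture():
    """A small high-LD founder-mosaic panel and its fallback map."""
    return generate_fixture(
        FixtureSpec(n_loci=150, m_samples=16, n_founders=4, seed=20)
    )
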