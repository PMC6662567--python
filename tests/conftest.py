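import numpy as np
import pytest

from tetrabin.synthetic_eval import CommunitySpec, generate_community

# coverage directions chosen well apart so 3-sample depth profiles are
# informative for every genome (Pearson correlation is scale-invariant and
# cannot separate near-parallel profiles)
SEPARATED_COVERAGE = np.array(
    [
        [60, 10, 10],
        [10, 60, 10],
        [10, 10, 60],
        [45, 45, 8],
        [45, 8, 45],
        [8, 45, 45],
        [60, 30, 10],
        [10, 30, 60],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def small_community():
    """Five genomes x 300 kb x 3 samples: quick end-to-end fixture."""
    spec = CommunitySpec(
        n_genomes=5,
        genome_length=300_000,
        n_samples=3,
        coverage_matrix=SEPARATED_COVERAGE[:5] / 1.5,
        seed=42,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def recruit_community():
    """Eight genomes x 1 Mb x 3 samples with separated coverage directions."""
    spec = CommunitySpec(
        n_genomes=8,
        genome_length=1_000_000,
        n_samples=3,
        coverage_matrix=SEPARATED_COVERAGE,
        seed=11,
    )
    return generate_community(spec)
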