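import numpy as np
import pytest

from snvancestry import (
    GenotypeMatrix,
    SimulationConfig,
    SyntheticWorldConfig,
    VariantKey,
    generate_synthetic_world,
    simulate_individuals,
)


@pytest.fixture(scope="session")
def flat_world():
    """Three well-diverged populations, 300 SNVs."""
    cfg = SyntheticWorldConfig(
        n_populations=3, n_variants=300, divergence=0.2, seed=11
    )
    aft, hierarchy = generate_synthetic_world(cfg)
    assert hierarchy is None
    return aft


@pytest.fixture(scope="session")
def flat_cohort(flat_world):
    return simulate_individuals(
        flat_world, SimulationConfig(n_per_population=40, seed=12)
    )


@pytest.fixture(scope="session")
def nested_world():
    """Two continents x two subpopulations, 400 SNVs."""
    cfg = SyntheticWorldConfig(
        n_populations=2,
        n_variants=400,
        divergence=0.2,
        seed=21,
        n_subpopulations_per=2,
        sub_divergence=0.05,
    )
    return generate_synthetic_world(cfg)


@pytest.fixture(scope="session")
def nested_cohort(nested_world):
    aft, _hierarchy = nested_world
    return simulate_individuals(
        aft, SimulationConfig(n_per_population=40, seed=22)
    )


def make_matrix(values, labels=None, chrom="1", build="synthetic"):
    """Small GenotypeMatrix from a dense array; variants at pos 1..m."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    variants = [VariantKey(chrom, j + 1, "A", "G", build) for j in range(m)]
    samples = [f"s{i}" for i in range(n)]
    label_map = None
    if labels is not None:
        label_map = {s: lab for s, lab in zip(samples, labels)}
    return GenotypeMatrix(
        variants=variants, samples=samples, values=values, labels=label_map
    )
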