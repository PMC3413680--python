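import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from gbaselect import (
    ExperimentMap,
    ExpressionCollection,
    ExpressionMatrix,
    GenePartition,
    SelectionParams,
    SyntheticSpec,
    default_experiment_design,
    generate_collection,
)


@pytest.fixture(scope="session")
def planted():
    """The standard planted collection: 40 category / 200 background genes,
    4 relevant + 16 irrelevant experiments of 6 arrays, signal/noise = 2."""
    spec = SyntheticSpec(rng_seed=0)
    collection, truth = generate_collection(spec)
    return spec, collection, truth


@pytest.fixture(scope="session")
def planted_params():
    return SelectionParams(k_seeds=10, significance=0.05, rng_seed=0)


@pytest.fixture(scope="session")
def noise_collection():
    """Pure-noise collection (no planted signal anywhere)."""
    spec = SyntheticSpec(
        n_category_genes=20,
        n_background_genes=60,
        experiments=default_experiment_design(2, 6, 4),
        signal_sd=0.0,
        rng_seed=7,
    )
    return generate_collection(spec)


@pytest.fixture()
def tiny_collection():
    """Hand-built 5-gene, 2-experiment collection with known values."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(5, 7))
    matrix = ExpressionMatrix(
        values,
        [f"g{i}" for i in range(5)],
        [f"a{i}" for i in range(7)],
    )
    experiments = ExperimentMap(
        {"a0": "E1", "a1": "E1", "a2": "E1", "a3": "E1",
         "a4": "E2", "a5": "E2", "a6": "E2"}
    )
    return ExpressionCollection(matrix, experiments)


@pytest.fixture()
def tiny_partition():
    return GenePartition(["g0", "g1", "g2"], ["g3", "g4"])
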