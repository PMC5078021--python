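import numpy as np
import pytest

from tlsea.io import RunConfig
from tlsea.similarity import SimilarityMatrix
from tlsea.simulate import BaselineSimilarityModel, FixtureSpec, generate_matrix_universe


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def null_model():
    return BaselineSimilarityModel()


@pytest.fixture
def small_config():
    """Sampling configuration small enough for per-test background runs."""
    return RunConfig(
        n_lengths=40, reps_per_length=100, length_range=(5, 60), seed=7
    )


@pytest.fixture
def random_matrix(rng, null_model):
    """A 60x20 null similarity matrix."""
    return SimilarityMatrix(
        [f"R{i:03d}" for i in range(60)],
        [f"C{i:03d}" for i in range(20)],
        null_model.draw(rng, (60, 20)),
    )


@pytest.fixture
def planted_universe():
    """Matrix-level universe with one strongly planted protein among nulls."""
    spec = FixtureSpec(
        n_phenotype_actives=25,
        n_target_compounds=400,
        n_background_compounds=400,
        n_proteins=10,
        ligand_set_size_range=(10, 30),
        planted_proteins=[("PLANT", 0.4)],
        seed=3,
    )
    return generate_matrix_universe(spec)
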