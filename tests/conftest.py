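import numpy as np
import pytest

from temposeg.grid import ExperimentDesign, GridSpec, default_levels, reduced_validation_design
from temposeg.generator import GeneratorConfig, build_bank
from temposeg.latent import batch_synthesize


@pytest.fixture(scope="session")
def full_grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=4, n_cols=4, n_frames=12)


@pytest.fixture(scope="session")
def latent_bank_full(full_grid):
    """Latent-factor bank over the full 45-pair design, 8 variants each."""
    design = ExperimentDesign(levels=tuple(default_levels()), n_variants=8)
    return batch_synthesize(design, full_grid, seed=321)


@pytest.fixture(scope="session")
def reduced_generator_bank(full_grid):
    """Optimized bank over nine specs spanning the design, two variants each.

    Uses the generator's default configuration; shared by the validation
    checks so the (slowish) optimization runs once per session.
    """
    return build_bank(
        reduced_validation_design(), n_variants=2, grid=full_grid,
        config=GeneratorConfig(), seed=2024,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
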