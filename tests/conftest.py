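import numpy as np
import pytest

from ratpheno.synth import SynthesisRecipe


@pytest.fixture
def recipe():
    """Default synthesis recipe, fixed seed."""
    return SynthesisRecipe(seed=7)


@pytest.fixture
def noiseless_recipe():
    """Recipe with every noise source switched off (exact generative law)."""
    return SynthesisRecipe(
        seed=7, noise_cv=0.0, bm_muscle_cv=0.0, bm_constant_cv=0.0, tl_sd_mm=0.0
    )


@pytest.fixture
def one_timepoint_recipe():
    return SynthesisRecipe(
        seed=11, n_per_group=30, timepoints=("6mo",), tl_mean_mm={"6mo": 40.0}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
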