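import numpy as np
import pytest

import nephroscreen as ns


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture(scope="session")
def small_image():
    """A deterministic 5-cell synthetic image with moderate punctateness."""
    return ns.generate_cell_image(5, chromatin_punctateness=0.5, seed=7)


@pytest.fixture(scope="session")
def small_panel():
    """A tiny noiseless dose panel with two informative features."""
    spec = ns.SyntheticPanelSpec(n_toxic=2, n_nontoxic=2, n_features=6,
                                 n_informative=2, replicate_noise_sd=0.0,
                                 n_replicates=2, seed=11)
    panel, compounds = ns.generate_dose_panel(spec)
    return spec, panel, compounds


@pytest.fixture(scope="session")
def planted_matrix():
    """Default-scale matrix with a strong redundant 4-feature signal."""
    spec = ns.SyntheticPanelSpec(effect_size=3.0, seed=5)
    matrix, labels = ns.generate_dmax_matrix(spec, effect_structure="shared")
    return spec, matrix, labels


def random_glcm(rng, n_levels=8):
    """A random normalized GLCM for oracle comparisons."""
    counts = rng.integers(0, 20, size=(n_levels, n_levels)).astype(float)
    counts[rng.integers(0, n_levels), rng.integers(0, n_levels)] += 1  # nonempty
    return ns.GLCMatrix(counts=counts, offset=(0, 1), n_levels=n_levels)
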