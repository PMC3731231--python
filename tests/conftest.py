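import numpy as np
import pytest

from eqtlcre.pipeline import residualize_study
from eqtlcre.simulate import simulate_study_set
from eqtlcre.tiers import ld_blocks


@pytest.fixture(scope="session")
def small_study():
    """A modest planted study set shared across integration tests."""
    return simulate_study_set(n_genes=40, n_samples=150, seed=11,
                              effect_r2=0.2, eqtl_fraction=0.6,
                              two_tier_fraction=0.25)


@pytest.fixture(scope="session")
def small_blocks(small_study):
    return {c: ld_blocks(r).block_index for c, r in small_study.rmaps.items()}


@pytest.fixture(scope="session")
def small_residuals(small_study):
    out = {}
    for sid, intens in small_study.expression.items():
        out[sid], _ = residualize_study(intens, knn_k=10, pve_delta=0.01)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
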