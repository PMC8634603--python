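import numpy as np
import pytest

import connectoscope as cs


@pytest.fixture(scope="session")
def gt_small():
    """Compact synthetic cortex used across modules (30 areas)."""
    return cs.generate_ground_truth(
        n_areas=30, sigma_log10=0.4, kappa=20, seed=7
    )


@pytest.fixture(scope="session")
def injections_small(gt_small):
    return [cs.generate_injection(t, gt_small) for t in range(30)]


@pytest.fixture(scope="session")
def matrices_small(injections_small, gt_small):
    return cs.build_matrices(injections_small, gt_small.area_names)


@pytest.fixture(scope="session")
def edge_complete_small(matrices_small):
    return cs.build_edge_complete(matrices_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
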