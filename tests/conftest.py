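import numpy as np
import pytest

from hsicad import hsio, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny mixed cohort (3 colon incl. 1 cancer-free, 2 EG) at 32x32."""
    cfg = synthetic.CohortConfig(
        n_colon=3, n_colon_no_cancer=1, n_eg=2, height=32, width=32, master_seed=11
    )
    manifest, data = synthetic.simulate_cohort(cfg)
    return cfg, manifest, data


@pytest.fixture(scope="session")
def separable_cohort_6():
    """Six-patient strongly separable cohort for classifier recovery tests."""
    cfg = synthetic.separable_config(
        n_colon=3, n_colon_no_cancer=0, n_eg=3, height=64, width=64, master_seed=21
    )
    manifest, data = synthetic.simulate_cohort(cfg)
    return cfg, manifest, data


@pytest.fixture()
def ones_cube():
    return hsio.Hypercube(
        values=np.ones((4, 4, 100), dtype=np.float32), grid=hsio.default_grid(100)
    )
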