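import numpy as np
import pytest

from cacgrs.synthetic_cohort import preset_config, simulate


@pytest.fixture(scope="session")
def small_clinical_bundle():
    """One modest clinical cohort shared by read-only tests."""
    cfg = preset_config("luric", seed=101, n_samples=800, n_meta_snps=50)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_autopsy_bundle():
    """TSDS-flavor cohort: calcification outcomes, lifestyle missingness."""
    cfg = preset_config("tsds", seed=202, n_meta_snps=50)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
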