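import numpy as np
import pytest

import prsfusion as pf


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: fast enough for unit tests, large enough for the
    planted reference correlation to be detectable."""
    return pf.SimConfig(
        n_subjects=300,
        n_snps=100,
        ld_block_size=5,
        n_voxels_per_modality=(400, 400),
        n_sources=5,
        target_ref_correlation=0.3,
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return pf.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_decomp(small_study):
    cfg = pf.FusionConfig(n_components=5, seed=7, n_ica_restarts=4)
    study = small_study
    x1 = pf.regress_covariates(study["x1"], study["covariates"],
                               ["age", "sex", "site", "mean_fd"])
    x2 = pf.regress_covariates(study["x2"], study["covariates"],
                               ["age", "sex", "site", "mean_fd"])
    return pf.select_component(pf.fuse_with_reference(x1, x2, study["prs"], cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
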