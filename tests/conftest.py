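import numpy as np
import pytest

import famcombine as fc


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_design():
    """A modest mixed design with a few causal SNPs (shared, read-only)."""
    rng = np.random.default_rng(7)
    pop = fc.PopulationConfig(n_snps=40, n_unrelated=300, n_trios=60)
    mafs = fc.draw_mafs(pop, rng)
    model = fc.default_liability_model(mafs, causal_fraction=0.1, rng=rng)
    sample, truth = fc.generate_replicate(pop, model, rng, mafs=mafs)
    return sample, truth, model


@pytest.fixture(scope="session")
def null_design():
    """Null design: no causal SNPs, common-ish MAFs for stable fits."""
    rng = np.random.default_rng(11)
    pop = fc.PopulationConfig(
        n_snps=30, n_unrelated=300, n_trios=60,
        maf_spectrum="uniform", spectrum_params={"low": 0.05, "high": 0.5},
    )
    mafs = fc.draw_mafs(pop, rng)
    model = fc.LiabilityModel(mafs=mafs, betas=np.zeros(30))
    model.threshold = fc.calibrate_threshold(model, rng=rng)
    sample, truth = fc.generate_replicate(pop, model, rng, mafs=mafs)
    return sample, truth, model
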