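import pytest

import strawinv as si


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Small noiseless synthetic study: generated straw lies exactly on the curve."""
    return si.SyntheticConfig(seed=11, noise_cv=0.0, n_obs_per_region=60,
                              n_cities_per_region=4)


@pytest.fixture(scope="session")
def noiseless_models(noiseless_cfg):
    obs = [o for r in si.Region for o in si.generate_observations(noiseless_cfg, r)]
    return {r: si.fit_straw_model(obs, r) for r in si.Region}


@pytest.fixture(scope="session")
def small_cities(noiseless_cfg):
    return si.generate_city_table(noiseless_cfg)


@pytest.fixture
def even_shares():
    return si.DisposalShares(0.5, 0.3, 0.2)
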