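import numpy as np
import pytest

from nirselect import spectral_space, synthetic


@pytest.fixture(scope="session")
def small_config():
    # compact population: fast for unit tests, keeps the 3-cultivar /
    # weekly-ripening structure intact
    return synthetic.SimulationConfig(n_samples=60, n_bands=64, seed=11)


@pytest.fixture(scope="session")
def small_population(small_config):
    return synthetic.generate_population(small_config)


@pytest.fixture(scope="session")
def small_scores(small_population):
    ds = small_population.to_absorbance()
    pca = spectral_space.fit_pca(ds.spectra, target_explained=0.99)
    return pca, pca.transform(ds.spectra, ds.sample_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
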