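import numpy as np
import pytest

from subseg.phantom import (DomainSpec, PhantomConfig, make_atlas, make_subject,
                            scanner_a, scanner_b)


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Desk-scale phantom geometry for fast tests (48^3 grid)."""
    return PhantomConfig(
        grid_shape=(48, 48, 48),
        structure_radii=(6.0, 5.2, 4.5, 3.9, 3.3, 2.7, 2.2),
        subject_jitter_sd=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def domain_a() -> DomainSpec:
    return scanner_a()


@pytest.fixture(scope="session")
def domain_b() -> DomainSpec:
    return scanner_b()


@pytest.fixture(scope="session")
def tiny_subject(tiny_config, domain_a):
    return make_subject(tiny_config, domain_a, subject_seed=0)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config, domain_a):
    labs = [make_subject(tiny_config, domain_a, s)[1] for s in range(3)]
    return make_atlas(labs, smoothing_sd=2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
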