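import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crowdaffect as ca

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-config synthetic campaign shared across tests."""
    return ca.generate(ca.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def valence_study_bundle():
    """Single-population valence-only campaign (60 pictures, 40 ratings)."""
    cfg = ca.GeneratorConfig(
        n_pictures=60,
        n_workers=60,
        populations={"specialized": 1.0},
        pool_range=(40, 40),
        dimensions=("valence",),
        seed=21,
    )
    return ca.generate(cfg)


@pytest.fixture()
def tiny_ratings_csv(tmp_path):
    path = tmp_path / "ratings.csv"
    path.write_text(
        "worker,picture,dimension,rating,population,batch\n"
        "w1,p1,valence,2,specialized,page0\n"
        "w1,p2,valence,8,specialized,page0\n"
        "w2,p1,valence,3,general,page0\n"
    )
    return path


def random_matrix(rng: np.random.Generator, n=None, k=None):
    n = n or int(rng.integers(2, 11))
    k = k or int(rng.integers(2, 7))
    return rng.integers(1, 10, size=(n, k)).astype(float) + rng.normal(
        0, 0.25, size=(n, k)
    )
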