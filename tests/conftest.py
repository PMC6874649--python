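import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pollinet import VisitMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_net() -> VisitMatrix:
    """2 plants x 2 bees worked example: rows (2,0) and (2,4)."""
    return VisitMatrix(("p1", "p2"), ("b1", "b2"),
                       np.array([[2, 0], [2, 4]]), network_id="small")


@pytest.fixture
def diag_net() -> VisitMatrix:
    """Perfect reciprocal specialization."""
    return VisitMatrix(("p1", "p2"), ("b1", "b2"),
                       np.array([[5, 0], [0, 5]]), network_id="diag")


def random_net(rng: np.random.Generator, n_plants=8, n_bees=10,
               total=200) -> VisitMatrix:
    """Small random network helper used across test modules."""
    from pollinet.synthetic import SyntheticConfig, gen_network

    cfg = SyntheticConfig(
        n_plants=n_plants, n_bees=n_bees, total_visits=total,
        plant_abundance_sigma=1.0, bee_abundance_sigma=1.0,
        specialization=0.3, seed=int(rng.integers(2**31)),
    )
    return gen_network(cfg)
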