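import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_nucleus_specs(n, seed=7, with_dents=True):
    """Seeded family of realistic nucleus specs shared across suites."""
    from nucleostress.synthetic import NucleusSpec

    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        modes = tuple(
            (int(k), rng.uniform(0.02, 0.08), rng.uniform(0, 2 * np.pi))
            for k in rng.choice([2, 3, 4, 5], 2, replace=False))
        dents = ()
        if with_dents:
            dents = tuple(
                (rng.uniform(0, 2 * np.pi), rng.uniform(1.5, 4.0),
                 rng.uniform(0.5, 1.2))
                for _ in range(rng.integers(0, 3)))
        specs.append(NucleusSpec(base_radius=8.0, fourier_modes=modes,
                                 dents=dents, seed=i))
    return specs
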