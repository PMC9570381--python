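import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppsaxs import CoreShellSpec, ParticleCloud, generate_core_shell

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def make_cloud():
    """Factory for random weighted clouds in a ball (coordinates in pm)."""

    def _make(
        n: int,
        seed: int = 0,
        radius_pm: float = 10_800.0,
        integer_coords: bool = False,
        integer_weights: bool = False,
    ) -> ParticleCloud:
        rng = np.random.default_rng(seed)
        r = radius_pm * np.cbrt(rng.random(n))
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pos = r[:, None] * v
        if integer_coords:
            pos = np.floor(pos + 0.5)
        if integer_weights:
            w = rng.integers(-5, 6, size=n).astype(float)
        else:
            w = rng.uniform(-0.1, 0.1, size=n)
        return ParticleCloud(pos, w, "pm")

    return _make


@pytest.fixture(scope="session")
def small_core_shell():
    """A modest core-shell cloud with the reference radii and contrasts."""
    return generate_core_shell(CoreShellSpec(n_particles=5_000, seed=11))
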