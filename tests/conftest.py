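import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_scenario():
    """Noise-free field, disjoint size-homogeneous particles: the regime in
    which detection must reproduce ground truth exactly."""
    from agnor.simulate import ImageScenario

    return ImageScenario(
        n_nuclei=50,
        agnor_count_distribution=("poisson", 3.0),
        agnor_radius_range=(0.45, 0.60),
        conglomerate_probability=0.0,
        noise_sd=0.0,
    )


@pytest.fixture()
def circle_nucleus():
    """A 150-grey circular nucleus of radius 16 px on a 205-grey background,
    with a painter for dark anti-aliased disks."""
    img = np.full((48, 48), 205.0)
    yy, xx = np.mgrid[0:48, 0:48]
    mask = (yy - 24) ** 2 + (xx - 24) ** 2 <= 16**2
    img[mask] = 150.0

    def paint(*disks, particle_intensity=40.0):
        out = img.copy()
        cov = np.zeros_like(out)
        for cy, cx, r in disks:
            d = np.hypot(yy - cy, xx - cx)
            cov = np.maximum(cov, np.clip(r - d + 0.5, 0.0, 1.0))
        cov[~mask] = 0.0
        out = out + (particle_intensity - out) * cov
        return np.clip(np.round(out), 0, 255).astype(np.uint8)

    return img.astype(np.uint8), mask, paint
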