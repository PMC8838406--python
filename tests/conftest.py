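import numpy as np
import pytest

from vesselseg.phantom import (
    PhantomSpec,
    VesselSegment,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """150x160 gray phantom with a thick and a thin vessel, mild noise."""
    spec = PhantomSpec(
        height=150,
        width=160,
        fov_radius_fraction=0.9,
        vessel_segments=(
            VesselSegment(start=(30.0, 20.0), end=(120.0, 140.0), width=5.0, depth=0.3),
            VesselSegment(start=(110.0, 25.0), end=(40.0, 130.0), width=1.5, depth=0.25),
        ),
        background_level=0.55,
        illumination_gradient_amplitude=0.08,
        noise_sigma=0.01,
        rng_seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_color_phantom():
    spec = PhantomSpec(
        height=120,
        width=130,
        fov_radius_fraction=0.9,
        vessel_segments=(
            VesselSegment(start=(20.0, 15.0), end=(100.0, 115.0), width=4.0, depth=0.3),
        ),
        noise_sigma=0.01,
        rng_seed=11,
    )
    return generate_phantom(spec, color=True)


def straight_vessel_image(
    size: int,
    angle_deg: float,
    width: float,
    depth: float = 0.3,
    background: float = 0.6,
) -> np.ndarray:
    """Noiseless dark straight vessel through the center at a given angle.

    The vessel extends along the direction (sin a, cos a) in (col, row)
    coordinates, which is the axis a matched-filter kernel at angle ``a``
    is aligned with.
    """
    import math

    sigma_v = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    c = (size - 1) / 2.0
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    a = math.radians(angle_deg)
    # signed distance from the center line with direction (sin a, cos a)
    d = (xs - c) * math.cos(a) - (ys - c) * math.sin(a)
    return background - depth * np.exp(-(d * d) / (2.0 * sigma_v * sigma_v))
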