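"""Synthetic fundus phantoms with pixel-exact vessel ground truth.

A phantom emulates the geometry and photometry of a fundus photograph at
the level the segmentation pipeline cares about: dark vessels of graded
width on a brighter background, a circular camera field of view (FOV)
surrounded by near-black, smooth uneven illumination, and additive sensor
noise.  Every vessel has an inverted-Gaussian cross-section — the profile
the Gaussian matched filter is derived for — so filter-scale selectivity
is analytically predictable.

Vessel width is given as full width at half maximum (FWHM) in pixels;
the Gaussian profile standard deviation is ``width / (2 sqrt(2 ln 2))``.
The ground-truth mask marks pixels where the noiseless vessel field
exceeds half the local peak depth, i.e. pixels within ``width / 2`` of a
vessel centerline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .thresholding import GrayHistogram

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class VesselSegment:
    """Straight vessel piece: endpoints in (row, col), FWHM width, contrast depth."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float
    depth: float


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 585
    width: int = 565
    fov_radius_fraction: float = 0.92
    vessel_segments: tuple[VesselSegment, ...] = ()
    background_level: float = 0.55
    illumination_gradient_amplitude: float = 0.10
    noise_sigma: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigurationError("phantom dimensions must be positive")
        if not 0.0 < self.fov_radius_fraction <= 1.0:
            raise ConfigurationError("fov_radius_fraction must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        limit = min(self.height, self.width) / 4.0
        for seg in self.vessel_segments:
            if not 0.0 < seg.width <= limit:
                raise ConfigurationError(
                    f"vessel width {seg.width} outside (0, {limit}]"
                )
            if seg.depth <= 0:
                raise ConfigurationError("vessel contrast depth must be positive")


@dataclass(frozen=True)
class Phantom:
    """Generated image plus pixel-exact ground truth and FOV mask."""

    image: np.ndarray  # float in [0,1]; (H,W) gray or (H,W,3) color
    truth_mask: np.ndarray  # bool (H,W), True = vessel
    fov_mask: np.ndarray  # bool (H,W), True = inside field of view
    spec: PhantomSpec = field(repr=False, default=PhantomSpec())


def _segment_distance(
    rows: np.ndarray, cols: np.ndarray, seg: VesselSegment
) -> np.ndarray:
    """Euclidean distance from each pixel center to the segment."""
    r0, c0 = seg.start
    r1, c1 = seg.end
    dr, dc = r1 - r0, c1 - c0
    norm2 = dr * dr + dc * dc
    if norm2 == 0.0:
        return np.hypot(rows - r0, cols - c0)
    t = ((rows - r0) * dr + (cols - c0) * dc) / norm2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rows - (r0 + t * dr), cols - (c0 + t * dc))


def _vessel_fields(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless vessel darkening field and the half-peak-depth truth mask."""
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    depth_field = np.zeros((spec.height, spec.width))
    truth = np.zeros((spec.height, spec.width), dtype=bool)
    for seg in spec.vessel_segments:
        sigma_v = seg.width / FWHM_PER_SIGMA
        d = _segment_distance(rows, cols, seg)
        contribution = seg.depth * np.exp(-(d * d) / (2.0 * sigma_v * sigma_v))
        depth_field = np.maximum(depth_field, contribution)
        truth |= contribution > seg.depth / 2.0
    return depth_field, truth


def _illumination(spec: PhantomSpec) -> np.ndarray:
    """Broad Gaussian ramp centered off-axis: smooth uneven illumination."""
    if spec.illumination_gradient_amplitude == 0.0:
        return np.zeros((spec.height, spec.width))
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    cr, cc = 0.35 * spec.height, 0.35 * spec.width
    scale = 0.7 * max(spec.height, spec.width)
    bump = np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2.0 * scale * scale))
    return spec.illumination_gradient_amplitude * (bump - 0.5)


def _fov(spec: PhantomSpec) -> np.ndarray:
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    cr, cc = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    radius = spec.fov_radius_fraction * min(spec.height, spec.width) / 2.0
    return np.hypot(rows - cr, cols - cc) <= radius


def generate_phantom(spec: PhantomSpec, color: bool = False) -> Phantom:
    """Render a phantom; deterministic for a fixed ``spec.rng_seed``.

    With ``color=True`` a 3-channel image is produced in which the vessel
    signal lives predominantly in the green channel, the red channel is
    brighter with low vessel contrast, and the blue channel is dim and
    noisy — mirroring the channel statistics of real fundus photographs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    depth_field, truth = _vessel_fields(spec)
    illum = _illumination(spec)
    fov = _fov(spec)
    truth &= fov

    def render(base: float, vessel_gain: float, noise_gain: float) -> np.ndarray:
        clean = base + illum - vessel_gain * depth_field
        img = np.where(fov, clean, 0.02)
        if spec.noise_sigma > 0:
            img = img + noise_gain * spec.noise_sigma * rng.standard_normal(
                img.shape
            )
        return np.clip(img, 0.0, 1.0)

    if color:
        red = render(min(0.95, spec.background_level + 0.25), 0.30, 1.0)
        green = render(spec.background_level, 1.0, 1.0)
        blue = render(max(0.10, spec.background_level - 0.35), 0.15, 2.5)
        image = np.stack([red, green, blue], axis=-1)
    else:
        image = render(spec.background_level, 1.0, 1.0)
    return Phantom(image=image, truth_mask=truth, fov_mask=fov, spec=spec)


def random_phantom_spec(
    rng_seed: int,
    height: int = 585,
    width: int = 565,
    n_main: int = 6,
    n_branches: int = 10,
    noise_sigma: float = 0.02,
    illumination_gradient_amplitude: float = 0.10,
) -> PhantomSpec:
    """Randomized vessel-tree phantom at fundus-photograph conditions.

    Main vessels (two-piece polylines, 4–6 px wide) radiate from a hub
    placed off-center like an optic disc; thinner branches (1–2.5 px)
    split off the mains at oblique angles.  Contrast depths are drawn in
    the range typical for the green channel of fundus images
    (roughly 0.2–0.3 against a 0.55 background).  The default image size
    matches a standard 565x585 fundus photograph.
    """
    rng = np.random.default_rng(rng_seed)
    cr, cc = (height - 1) / 2.0, (width - 1) / 2.0
    fov_fraction = 0.92
    fov_radius = fov_fraction * min(height, width) / 2.0

    def clip_to_fov(point: np.ndarray) -> tuple[float, float]:
        offset = point - np.array([cr, cc])
        dist = float(np.hypot(*offset))
        limit = 0.95 * fov_radius
        if dist > limit:
            offset *= limit / dist
        return (cr + offset[0], cc + offset[1])

    hub_angle = rng.uniform(0, 2 * math.pi)
    hub = np.array([cr, cc]) + 0.55 * fov_radius * np.array(
        [math.sin(hub_angle), math.cos(hub_angle)]
    )
    segments: list[VesselSegment] = []
    mains: list[VesselSegment] = []
    for _ in range(n_main):
        direction = rng.uniform(0, 2 * math.pi)
        width_px = rng.uniform(4.0, 6.0)
        depth = rng.uniform(0.22, 0.32)
        start = hub.copy()
        for piece in range(2):
            length = rng.uniform(0.35, 0.6) * fov_radius
            direction += rng.uniform(-0.5, 0.5)
            end = start + length * np.array(
                [math.sin(direction), math.cos(direction)]
            )
            seg = VesselSegment(
                start=clip_to_fov(start),
                end=clip_to_fov(end),
                width=width_px * (0.75**piece),
                depth=depth,
            )
            segments.append(seg)
            mains.append(seg)
            start = np.array(clip_to_fov(end))
    for _ in range(n_branches):
        parent = mains[rng.integers(len(mains))]
        t = rng.uniform(0.2, 0.9)
        p0 = np.array(parent.start) + t * (
            np.array(parent.end) - np.array(parent.start)
        )
        parent_dir = math.atan2(
            parent.end[0] - parent.start[0], parent.end[1] - parent.start[1]
        )
        direction = parent_dir + rng.choice([-1, 1]) * rng.uniform(0.5, 1.1)
        length = rng.uniform(40.0, 120.0)
        p1 = p0 + length * np.array([math.sin(direction), math.cos(direction)])
        segments.append(
            VesselSegment(
                start=clip_to_fov(p0),
                end=clip_to_fov(p1),
                width=rng.uniform(1.0, 2.5),
                depth=rng.uniform(0.18, 0.28),
            )
        )
    return PhantomSpec(
        height=height,
        width=width,
        fov_radius_fraction=fov_fraction,
        vessel_segments=tuple(segments),
        background_level=0.55,
        illumination_gradient_amplitude=illumination_gradient_amplitude,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def generate_histogram_fixture(n_modes: int, rng_seed: int) -> GrayHistogram:
    """256-bin mixture-of-Gaussians histogram with well-separated modes.

    Mode centers are jittered around the centers of ``n_modes`` equal
    partitions of the gray range, so for small mode widths adjacent modes
    are separated by clear valleys — the regime in which exhaustive
    multilevel Otsu has an unambiguous optimum.
    """
    if not 1 <= n_modes <= 6:
        raise ConfigurationError("n_modes must be between 1 and 6")
    rng = np.random.default_rng(rng_seed)
    levels = np.arange(256, dtype=float)
    p = np.zeros(256)
    span = 256.0 / n_modes
    for k in range(n_modes):
        center = (k + 0.5) * span + rng.uniform(-0.1, 0.1) * span
        sigma = rng.uniform(span / 16.0, span / 8.0)
        weight = rng.uniform(0.5, 1.0)
        p += weight * np.exp(-((levels - center) ** 2) / (2.0 * sigma * sigma))
    p /= p.sum()
    return GrayHistogram(probabilities=p)
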