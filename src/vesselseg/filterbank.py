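"""Rotated multi-scale Gaussian matched filters for vessel enhancement.

A vessel segment shorter than its local curvature radius looks like a
straight dark line with a Gaussian cross-section.  The matched filter
for that template is an inverted Gaussian ridge of scale sigma (the
cross-section spread) and length L (the segment length):

    K_theta(p) = -exp(-u^2 / (2 sigma^2))   for p-bar = (u, v) in Z,

where (u, v) are the coordinates of grid point p rotated by theta and
the support Z is the rectangle |u| <= 3 sigma, |v| <= L/2.  The mean of
the in-support values is subtracted so every kernel is zero-mean and
constant backgrounds give exactly zero response; with the negative sign
a dark vessel center produces a positive response.  A bank of rotations
(every 15 degrees by default, 12 orientations spanning 180) is applied
and each pixel keeps its maximum orientation response.

Responses at three scales — coarse (main trunks), intermediate, and fine
(capillary detail) — are fused by a convex weighted sum and min–max
rescaled to [0, 1].

Small-scale degeneracy: for sigma small enough that 3 sigma < 1/2, the
support at axis-aligned angles (0 and 90 degrees) collapses to a single
line of constant u = 0; mean subtraction then annihilates the kernel
entirely and those two orientations contribute zero response.  At other
angles the support is a thin oriented strip with genuine cross-section
variation.  This is what the template definition yields and is kept
as-is rather than silently altering the scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ParameterError, ShapeError


@dataclass(frozen=True)
class KernelSpec:
    """Scale, length and orientation sampling of one matched-filter bank."""

    sigma: float = 1.9
    length: float = 9.0
    n_orientations: int = 12
    angle_step: float = 15.0

    def validate(self) -> None:
        if self.sigma <= 0 or self.length <= 0:
            raise ConfigurationError("sigma and length must be positive")
        if self.n_orientations < 1:
            raise ConfigurationError("need at least one orientation")
        if abs(self.n_orientations * self.angle_step - 180.0) > 1e-9:
            raise ConfigurationError(
                "orientations must tile 180 degrees: "
                f"{self.n_orientations} x {self.angle_step} != 180"
            )

    @property
    def angles(self) -> tuple[float, ...]:
        return tuple(i * self.angle_step for i in range(self.n_orientations))


@dataclass(frozen=True)
class FusionConfig:
    """Scales and convex weights of the three-scale fusion."""

    sigmas: tuple[float, float, float] = (1.9, 0.5, 0.13)
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def validate(self) -> None:
        if len(self.sigmas) != len(self.weights):
            raise ConfigurationError("sigmas and weights must have equal length")
        if any(s <= 0 for s in self.sigmas):
            raise ConfigurationError("fusion sigmas must be positive")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("fusion weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("fusion weights must sum to 1")


def build_kernel(spec: KernelSpec, theta: float) -> np.ndarray:
    """Realize the zero-mean matched-filter kernel at orientation ``theta``.

    ``theta`` is in degrees, in [0, 180).  Grid points are integer pixel
    offsets (x = column, y = row); a point is in-support iff its rotated
    coordinates (u, v) satisfy |u| <= 3 sigma and |v| <= L/2.  The
    returned array is cropped to the support's bounding box;
    out-of-support entries are 0.
    """
    spec.validate()
    if not 0.0 <= theta < 180.0:
        raise ParameterError(f"theta must lie in [0, 180), got {theta}")
    half_u = 3.0 * spec.sigma
    half_v = spec.length / 2.0
    radius = int(math.ceil(math.hypot(half_u, half_v)))
    ys, xs = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    th = math.radians(theta)
    cos_t, sin_t = math.cos(th), math.sin(th)
    u = xs * cos_t - ys * sin_t
    v = xs * sin_t + ys * cos_t
    # tolerance keeps half-integer bounds (L/2 with odd L) inclusive under
    # float rotation error
    tol = 1e-9
    support = (np.abs(u) <= half_u + tol) & (np.abs(v) <= half_v + tol)
    if not support.any():
        raise ConfigurationError("kernel support is empty")
    kernel = np.where(support, -np.exp(-(u * u) / (2.0 * spec.sigma**2)), 0.0)
    kernel[support] -= kernel[support].mean()
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    return kernel[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def build_filter_bank(spec: KernelSpec) -> dict[float, np.ndarray]:
    """All orientation kernels of one scale, keyed by angle in degrees."""
    return {theta: build_kernel(spec, theta) for theta in spec.angles}


def orientation_responses(image: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Stack of per-orientation filter responses, shape (n_orientations, H, W).

    The kernels are symmetric under point reflection, so convolution and
    correlation coincide; reflective boundary handling matches the
    preprocessing stage.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ShapeError("image must be finite")
    bank = build_filter_bank(spec)
    return np.stack(
        [
            ndimage.correlate(image, kernel, mode="reflect")
            for kernel in bank.values()
        ]
    )


def max_response(image: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Pixel-wise maximum response over all orientations of the bank."""
    return orientation_responses(image, spec).max(axis=0)


def argmax_orientation(image: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Angle (degrees) of the strongest-responding kernel at each pixel."""
    idx = orientation_responses(image, spec).argmax(axis=0)
    return np.asarray(spec.angles)[idx]


def fuse_scales(
    responses: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Convex combination of per-scale responses, rescaled to [0, 1].

    Responses are clamped at zero from below first (only positive
    matched-filter responses indicate vessel presence), then weighted,
    summed, and min–max normalized.
    """
    config = config or FusionConfig()
    config.validate()
    arrays = [np.asarray(r, dtype=float) for r in responses]
    if len({a.shape for a in arrays}) != 1:
        raise ShapeError(
            f"response shapes differ: {[a.shape for a in arrays]}"
        )
    fused = sum(
        w * np.maximum(a, 0.0) for w, a in zip(config.weights, arrays)
    )
    lo, hi = float(fused.min()), float(fused.max())
    if hi - lo < 1e-12:
        return np.zeros_like(fused)
    return (fused - lo) / (hi - lo)


def multiscale_response(
    image: np.ndarray,
    fusion: FusionConfig | None = None,
    kernel: KernelSpec | None = None,
) -> np.ndarray:
    """Max orientation response at each fusion scale, then fused map."""
    fusion = fusion or FusionConfig()
    kernel = kernel or KernelSpec()
    responses = tuple(
        max_response(
            image,
            KernelSpec(
                sigma=s,
                length=kernel.length,
                n_orientations=kernel.n_orientations,
                angle_step=kernel.angle_step,
            ),
        )
        for s in fusion.sigmas
    )
    return fuse_scales(responses, fusion)
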