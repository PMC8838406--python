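"""Multi-Scale Retinex (MSR) illumination correction and channel selection.

Fundus photographs suffer from smooth, uneven illumination that pushes
vessel and background gray levels into overlapping ranges.  Retinex
theory models the observed image as illumination times reflectance,
S = i * R; the reflectance — what segmentation actually wants — is
recovered as the log-ratio of the image to smoothed (surround-Gaussian)
versions of itself.  MSR averages that log-ratio over N surround scales:

    R_MSR = sum_n w_n (log S - log(S (*) F_n)),   sum_n w_n = 1,

with F_n a normalized Gaussian of standard deviation ``scales[n]`` and
(*) 2-D convolution (reflective boundary).  N = 3 with a small, medium
and large scale is the customary configuration and the default here.

After enhancement the green channel is extracted: in fundus images it
carries the highest vessel/background contrast (red is near-saturated,
blue is noisy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ChannelError, ConfigurationError


@dataclass(frozen=True)
class MSRConfig:
    """Surround scales, their weights, and the log-domain stabilizer.

    ``epsilon`` is a floor applied to pixel values before taking logs so
    true zeros are representable; values are clamped up to it, which
    keeps the log-ratio exactly invariant to global multiplicative gain
    on images already bounded below by ``epsilon``.
    """

    scales: tuple[float, ...] = (15.0, 80.0, 250.0)
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    epsilon: float = 1.0 / 255.0

    def validate(self) -> None:
        if len(self.scales) != len(self.weights):
            raise ConfigurationError("scales and weights must have equal length")
        if len(self.scales) == 0:
            raise ConfigurationError("need at least one surround scale")
        if any(s <= 0 for s in self.scales):
            raise ConfigurationError("surround scales must be positive")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("weights must sum to 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")


def _msr_channel(channel: np.ndarray, config: MSRConfig) -> np.ndarray:
    s = np.maximum(np.asarray(channel, dtype=float), config.epsilon)
    log_s = np.log(s)
    out = np.zeros_like(s)
    for scale, weight in zip(config.scales, config.weights):
        surround = ndimage.gaussian_filter(s, sigma=scale, mode="reflect")
        out += weight * (log_s - np.log(np.maximum(surround, config.epsilon)))
    return out


def _rescale01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def msr(
    image: np.ndarray, config: MSRConfig | None = None, rescale: bool = True
) -> np.ndarray:
    """Multi-Scale Retinex of a gray or color image.

    Applied per channel for 3-channel input.  By default the raw
    log-ratio response is min–max rescaled to [0, 1] per channel (the
    raw response is signed and unbounded); pass ``rescale=False`` to get
    the raw response, e.g. for invariance checks.
    """
    config = config or MSRConfig()
    config.validate()
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ConfigurationError("image must be finite")
    post = _rescale01 if rescale else (lambda x: x)
    if image.ndim == 2:
        return post(_msr_channel(image, config))
    if image.ndim == 3 and image.shape[2] == 3:
        return np.stack(
            [post(_msr_channel(image[..., c], config)) for c in range(3)],
            axis=-1,
        )
    raise ChannelError(f"expected (H,W) or (H,W,3) image, got shape {image.shape}")


def extract_green_channel(image: np.ndarray) -> np.ndarray:
    """Green channel (index 1 of RGB) of a 3-channel image, unchanged."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ChannelError(
            f"green-channel extraction needs an (H,W,3) image, got {image.shape}"
        )
    return image[..., 1]
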