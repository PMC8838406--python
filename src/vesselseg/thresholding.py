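"""Multilevel Otsu thresholding optimized by particle swarm search.

The segmentation stage picks ``m`` gray-level thresholds maximizing the
between-class variance

    sigma_B^2(t_1..t_m) = sum_k w_k (u_k - u_T)^2

where ``w_k`` and ``u_k`` are the probability mass and mean gray level of
class ``k`` (levels in ``(t_k, t_{k+1}]``) and ``u_T`` is the global mean.
For ``m = 1`` an exhaustive scan over the 255 candidate thresholds is
cheap; for ``m = 3`` the combinatorial space (~2.7M ordered triples over
256 levels) is searched with a canonical particle swarm: each particle is
a continuous point in ``[0, 254]^m``, moved by inertia plus attraction to
its personal best and the swarm's global best, and evaluated on its
repaired (rounded, sorted, deduplicated) integer projection.

The final multi-level image is re-binarized with single-threshold Otsu,
so the downstream vessel map is always binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateHistogramError,
    ParameterError,
)

N_LEVELS = 256

#: guard added inside floor-quantization so values that are exact
#: multiples of 1/255 land on their intended level despite float rounding
_QUANT_EPS = 1e-6


@dataclass(frozen=True)
class GrayHistogram:
    """256-bin gray-level distribution; probabilities sum to 1."""

    probabilities: np.ndarray
    counts: np.ndarray | None = None
    total: int | None = None

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (N_LEVELS,):
            raise ConfigurationError("histogram must have exactly 256 bins")
        if np.any(p < 0) or not np.isfinite(p).all():
            raise ConfigurationError("histogram probabilities must be finite and >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("histogram probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "GrayHistogram":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total == 0:
            raise DegenerateHistogramError("histogram has no pixels")
        return cls(probabilities=counts / total, counts=counts, total=total)

    @property
    def n_nonzero_bins(self) -> int:
        return int(np.count_nonzero(self.probabilities))


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings; defaults follow the standard published configuration."""

    population_size: int = 40
    inertia: float = 0.5
    accel: tuple[float, float] = (2.0, 2.0)
    max_iterations: int = 20
    rng_seed: int = 0
    velocity_clamp: float = 0.2
    dimension: int = 3

    def validate(self) -> None:
        if self.population_size < 1:
            raise ConfigurationError("population_size must be >= 1")
        if self.max_iterations < 0:
            raise ConfigurationError("max_iterations must be >= 0")
        if self.dimension < 1:
            raise ConfigurationError("dimension must be >= 1")
        if not 0.0 < self.velocity_clamp <= 1.0:
            raise ConfigurationError("velocity_clamp must lie in (0, 1]")


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping of the swarm."""

    positions: np.ndarray  # (N, D) continuous in [0, 254]
    velocities: np.ndarray  # (N, D)
    pbest_positions: np.ndarray  # (N, D)
    pbest_fitness: np.ndarray  # (N,)
    gbest_position: np.ndarray  # (D,)
    gbest_fitness: float
    iteration: int
    rng: np.random.Generator = field(repr=False, default=None)


def quantize256(values: np.ndarray) -> np.ndarray:
    """Map [0,1] floats to integer levels 0..255 by floor(v*255)."""
    levels = np.floor(np.asarray(values, dtype=float) * 255.0 + _QUANT_EPS)
    return np.clip(levels, 0, 255).astype(np.int64)


def histogram256(
    image: np.ndarray, mask: np.ndarray | None = None
) -> GrayHistogram:
    """Gray-level histogram of an image with values in [0, 1].

    When ``mask`` is given, only pixels with ``mask == True`` are counted
    (the convention for fundus images, where the black surround outside
    the field of view would otherwise dominate the lowest class).
    """
    image = np.asarray(image, dtype=float)
    values = image[np.asarray(mask, bool)] if mask is not None else image.ravel()
    if values.size == 0:
        raise DegenerateHistogramError("mask selects no pixels")
    counts = np.bincount(quantize256(values), minlength=N_LEVELS)
    return GrayHistogram.from_counts(counts)


def _check_ordered(thresholds: Sequence[int]) -> np.ndarray:
    t = np.asarray(thresholds, dtype=np.int64)
    if t.ndim != 1 or t.size < 1:
        raise ParameterError("need at least one threshold")
    if np.any(t < 0) or np.any(t > N_LEVELS - 2):
        raise ParameterError("thresholds must lie in [0, 254]")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ParameterError(f"thresholds must be strictly increasing, got {tuple(t)}")
    return t


def between_class_variance(
    hist: GrayHistogram, thresholds: Sequence[int]
) -> float:
    """sigma_B^2 for the class partition induced by ``thresholds``.

    Class ``k`` spans levels ``t_k + 1 .. t_{k+1}`` with ``t_0 = -1`` and
    ``t_{m+1} = 255``; empty classes contribute zero.
    """
    t = _check_ordered(thresholds)
    p = hist.probabilities
    levels = np.arange(N_LEVELS, dtype=float)
    u_t = float(levels @ p)
    edges = np.concatenate(([-1], t, [N_LEVELS - 1]))
    total = 0.0
    for k in range(edges.size - 1):
        lo, hi = edges[k] + 1, edges[k + 1] + 1
        w = p[lo:hi].sum()
        if w > 0:
            u = float(levels[lo:hi] @ p[lo:hi]) / w
            total += w * (u - u_t) ** 2
    return total


def class_moments(
    hist: GrayHistogram, thresholds: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class probability masses w_k and means u_k (0 for empty classes)."""
    t = _check_ordered(thresholds)
    p = hist.probabilities
    levels = np.arange(N_LEVELS, dtype=float)
    edges = np.concatenate(([-1], t, [N_LEVELS - 1]))
    ws, us = [], []
    for k in range(edges.size - 1):
        lo, hi = edges[k] + 1, edges[k + 1] + 1
        w = p[lo:hi].sum()
        ws.append(w)
        us.append(float(levels[lo:hi] @ p[lo:hi]) / w if w > 0 else 0.0)
    return np.asarray(ws), np.asarray(us)


def _variance_curve(hist: GrayHistogram) -> np.ndarray:
    """sigma_B^2 for every single threshold t in [0, 254], vectorized."""
    p = hist.probabilities
    levels = np.arange(N_LEVELS, dtype=float)
    w0 = np.cumsum(p)[:-1]
    s0 = np.cumsum(levels * p)[:-1]
    u_t = float(levels @ p)
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        u0 = np.where(w0 > 0, s0 / w0, 0.0)
        u1 = np.where(w1 > 0, (u_t - s0) / w1, 0.0)
    return w0 * (u0 - u_t) ** 2 + w1 * (u1 - u_t) ** 2


def otsu_single(hist: GrayHistogram) -> int:
    """Exhaustive argmax of sigma_B^2 over t in [0, 254]; smallest t on ties."""
    if hist.n_nonzero_bins < 2:
        raise DegenerateHistogramError(
            "single-threshold Otsu needs at least two occupied bins"
        )
    return int(np.argmax(_variance_curve(hist)))


def repair_position(position: np.ndarray) -> tuple[int, ...]:
    """Project a continuous swarm position onto a strictly ordered int tuple.

    Round to integers, clip to [0, 254], sort, then bump duplicates up by
    one level (and push back down from the top if that overflows 254).
    """
    t = np.sort(np.clip(np.rint(position).astype(np.int64), 0, N_LEVELS - 2))
    m = t.size
    for i in range(1, m):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    for i in range(m - 1, -1, -1):
        cap = (N_LEVELS - 2) - (m - 1 - i)
        if t[i] > cap:
            t[i] = cap
    for i in range(1, m):  # restore strict order after capping
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    return tuple(int(v) for v in t)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mirror out-of-range coordinates back into [lo, hi]."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def init_swarm(
    config: PSOConfig,
    fitness: Callable[[tuple[int, ...]], float],
) -> SwarmState:
    """Random swarm over [0, 254]^D with evaluated initial bests."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n, d = config.population_size, config.dimension
    hi = float(N_LEVELS - 2)
    vmax = config.velocity_clamp * hi
    positions = rng.uniform(0.0, hi, size=(n, d))
    velocities = rng.uniform(-vmax, vmax, size=(n, d))
    fitnesses = np.array([fitness(repair_position(x)) for x in positions])
    best = int(np.argmax(fitnesses))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fitnesses,
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fitnesses[best]),
        iteration=0,
        rng=rng,
    )


def pso_step(
    state: SwarmState,
    config: PSOConfig,
    fitness: Callable[[tuple[int, ...]], float],
) -> SwarmState:
    """One velocity/position update followed by fitness and best bookkeeping.

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);  x <- x + v,
    with fresh uniform r1, r2 per particle and dimension, velocities
    clamped to ±velocity_clamp of the gray range and positions reflected
    into [0, 254].
    """
    n, d = state.positions.shape
    hi = float(N_LEVELS - 2)
    vmax = config.velocity_clamp * hi
    c1, c2 = config.accel
    # draw order fixed for reproducibility: particle-major, dimension-minor,
    # r1 before r2
    r = state.rng.random(size=(n, d, 2))
    r1, r2 = r[..., 0], r[..., 1]
    v = (
        config.inertia * state.velocities
        + c1 * r1 * (state.pbest_positions - state.positions)
        + c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    v = np.clip(v, -vmax, vmax)
    x = _reflect(state.positions + v, 0.0, hi)

    fitnesses = np.array([fitness(repair_position(xi)) for xi in x])
    improved = fitnesses > state.pbest_fitness
    pbest_positions = np.where(improved[:, None], x, state.pbest_positions)
    pbest_fitness = np.where(improved, fitnesses, state.pbest_fitness)
    best = int(np.argmax(pbest_fitness))
    if pbest_fitness[best] > state.gbest_fitness:
        gbest_position = pbest_positions[best].copy()
        gbest_fitness = float(pbest_fitness[best])
    else:
        gbest_position, gbest_fitness = state.gbest_position, state.gbest_fitness
    return replace(
        state,
        positions=x,
        velocities=v,
        pbest_positions=pbest_positions,
        pbest_fitness=pbest_fitness,
        gbest_position=gbest_position,
        gbest_fitness=gbest_fitness,
        iteration=state.iteration + 1,
    )


def otsu_pso(
    hist: GrayHistogram, m: int = 3, config: PSOConfig | None = None
) -> tuple[int, ...]:
    """Best m-threshold combination found by the particle swarm.

    Initializes a random swarm, evaluates the between-class variance of
    each particle's repaired position, and runs ``max_iterations`` update
    steps; the global best is returned as a strictly ordered integer
    tuple.  Deterministic for a fixed ``config.rng_seed``.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    if hist.n_nonzero_bins < m + 1:
        raise DegenerateHistogramError(
            f"{m} thresholds need at least {m + 1} occupied bins"
        )
    config = replace(config or PSOConfig(), dimension=m)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(t: tuple[int, ...]) -> float:
        if t not in cache:
            cache[t] = between_class_variance(hist, t)
        return cache[t]

    state = init_swarm(config, fitness)
    for _ in range(config.max_iterations):
        state = pso_step(state, config, fitness)
    return repair_position(state.gbest_position)


def apply_thresholds(
    image: np.ndarray, thresholds: Sequence[int]
) -> np.ndarray:
    """Label each pixel with its class index 0..m under the thresholds.

    Pixel with quantized level ``l`` gets class ``k`` where
    ``t_k < l <= t_{k+1}`` (``t_0 = -inf``, ``t_{m+1} = +inf``).
    """
    t = _check_ordered(thresholds)
    levels = quantize256(image)
    return np.digitize(levels, t, right=True)


def render_labels(labels: np.ndarray, m: int) -> np.ndarray:
    """Render class labels 0..m at equally spaced gray levels in [0, 1].

    For m = 3 the representative levels are {0, 85, 170, 255}/255, which
    preserves class ordering for the single-threshold re-binarization.
    """
    reps = np.round(np.arange(m + 1) * 255.0 / m) / 255.0
    return reps[np.asarray(labels, dtype=np.int64)]
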