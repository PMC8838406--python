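"""Independent brute-force oracles used to validate the implementation.

Everything here is written directly from first principles (explicit
loops and dense enumeration) and deliberately shares no code with the
package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_otsu_single(p: np.ndarray) -> tuple[int, float]:
    """Double-loop single-threshold Otsu: best (t, sigma_B^2), smallest t on ties."""
    L = p.size
    u_t = sum(i * p[i] for i in range(L))
    best_t, best_v = 0, -1.0
    for t in range(L - 1):
        w0 = sum(p[i] for i in range(0, t + 1))
        w1 = sum(p[i] for i in range(t + 1, L))
        u0 = sum(i * p[i] for i in range(0, t + 1)) / w0 if w0 > 0 else 0.0
        u1 = sum(i * p[i] for i in range(t + 1, L)) / w1 if w1 > 0 else 0.0
        v = w0 * (u0 - u_t) ** 2 + w1 * (u1 - u_t) ** 2
        if v > best_v + 1e-15 * max(1.0, abs(best_v)):
            best_t, best_v = t, v
    return best_t, best_v


def direct_between_class_variance(p: np.ndarray, thresholds) -> float:
    """Loop-and-sum sigma_B^2 straight from the class definitions."""
    L = p.size
    u_t = sum(i * p[i] for i in range(L))
    edges = [-1, *thresholds, L - 1]
    total = 0.0
    for k in range(len(edges) - 1):
        lo, hi = edges[k] + 1, edges[k + 1]
        w = sum(p[i] for i in range(lo, hi + 1))
        if w > 0:
            u = sum(i * p[i] for i in range(lo, hi + 1)) / w
            total += w * (u - u_t) ** 2
    return total


def exhaustive_otsu3(
    p: np.ndarray, candidates: np.ndarray | None = None
) -> tuple[tuple[int, int, int], float]:
    """Exhaustive triple-loop search for the best 3-threshold combination.

    ``candidates`` restricts the scanned threshold levels (the optimum
    over all levels equals the optimum over boundaries between occupied
    levels, since fitness only depends on class membership).  Vectorized
    over the innermost loop to keep ~2.7M evaluations tractable.
    """
    L = p.size
    lv = np.arange(L, dtype=float)
    cp = np.concatenate(([0.0], np.cumsum(p)))
    cs = np.concatenate(([0.0], np.cumsum(lv * p)))
    u_t = cs[-1]
    cand = np.arange(L - 1) if candidates is None else np.asarray(candidates)

    def term(w, s):
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(w > 0, s / np.where(w > 0, w, 1.0), 0.0)
        return np.where(w > 0, w * (u - u_t) ** 2, 0.0)

    best_f, best_t = -1.0, None
    for i1, t1 in enumerate(cand[:-2]):
        v0 = float(term(cp[t1 + 1], cs[t1 + 1]))
        for t2 in cand[i1 + 1 : -1]:
            v1 = float(term(cp[t2 + 1] - cp[t1 + 1], cs[t2 + 1] - cs[t1 + 1]))
            t3 = cand[(cand > t2)]
            w2 = cp[t3 + 1] - cp[t2 + 1]
            s2 = cs[t3 + 1] - cs[t2 + 1]
            w3 = cp[L] - cp[t3 + 1]
            s3 = cs[L] - cs[t3 + 1]
            f = v0 + v1 + term(w2, s2) + term(w3, s3)
            j = int(np.argmax(f))
            if f[j] > best_f:
                best_f = float(f[j])
                best_t = (int(t1), int(t2), int(t3[j]))
    return best_t, best_f


def dense_gaussian_surround(image: np.ndarray, sigma: float) -> np.ndarray:
    """Reflect-padded dense convolution with a truncated Gaussian surround.

    Mirrors the standard separable construction: 1-D kernel sampled on
    integer offsets out to radius ``int(4 sigma + 0.5)``, normalized to
    sum 1, applied as the outer product, full dense double loop.
    """
    radius = int(4.0 * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    k1 = np.exp(-(offsets.astype(float) ** 2) / (2.0 * sigma * sigma))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(image, radius, mode="symmetric")
    h, w = image.shape
    out = np.zeros_like(image, dtype=float)
    for r in range(h):
        for c in range(w):
            out[r, c] = float(
                (padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1] * kernel).sum()
            )
    return out


def enumerate_kernel(sigma: float, length: float, theta_deg: float):
    """Grid enumeration of the rotated matched-filter template.

    Returns (points, raw_values): all integer offsets whose rotated
    coordinates (u, v) fall in |u| <= 3 sigma, |v| <= L/2, with the raw
    (pre-mean-subtraction) template value -exp(-u^2 / 2 sigma^2).
    """
    half_u, half_v = 3.0 * sigma, length / 2.0
    radius = int(math.ceil(math.hypot(half_u, half_v)))
    th = math.radians(theta_deg)
    points, values = [], []
    for y in range(-radius, radius + 1):
        for x in range(-radius, radius + 1):
            u = x * math.cos(th) - y * math.sin(th)
            v = x * math.sin(th) + y * math.cos(th)
            if abs(u) <= half_u + 1e-9 and abs(v) <= half_v + 1e-9:
                points.append((x, y))
                values.append(-math.exp(-(u * u) / (2.0 * sigma * sigma)))
    return points, values


def sliding_median(image: np.ndarray, size: int) -> np.ndarray:
    """Brute-force median filter with reflective boundary."""
    r = size // 2
    padded = np.pad(image.astype(float), r, mode="reflect")
    out = np.zeros_like(image, dtype=float)
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(padded[i : i + size, j : j + size])
    return out


def random_histogram(rng: np.random.Generator, sparse: bool = False) -> np.ndarray:
    """Random 256-bin probability vector; optionally with many empty bins."""
    p = rng.random(256)
    if sparse:
        mask = rng.random(256) < 0.85
        p[mask] = 0.0
        if np.count_nonzero(p) < 2:
            p[[10, 200]] = [1.0, 1.0]
    return p / p.sum()


def downsample_to_64_levels(p: np.ndarray) -> np.ndarray:
    """Aggregate groups of 4 adjacent levels onto the group's first level."""
    out = np.zeros_like(p)
    out[::4] = p.reshape(64, 4).sum(axis=1)
    return out
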