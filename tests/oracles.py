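"""Independent brute-force implementations used as oracles.

These deliberately avoid the vectorized code paths of the package: direct
double-loop convolution, exhaustive per-pixel directional scans with a
hand-written bilinear interpolation, breadth-first flood fill, and literal
vector summation.
"""

import math

import numpy as np


def _reflect_index(i: int, n: int) -> int:
    """scipy-style 'reflect' boundary (d c b a | a b c d | d c b a)."""
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def brute_gaussian_gradient(img: np.ndarray, sigma_px: float):
    """Direct (non-separable-free) convolution with sampled kernels."""
    radius = max(1, int(4.0 * sigma_px + 0.5))
    xs = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (xs / sigma_px) ** 2)
    g = g / g.sum()
    dg = -(xs / sigma_px**2) * g
    h, w = img.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            sx = 0.0
            sy = 0.0
            for a in range(-radius, radius + 1):
                for b in range(-radius, radius + 1):
                    # true convolution: kernel index = displacement of source
                    v = img[_reflect_index(r - a, h), _reflect_index(c - b, w)]
                    sx += g[a + radius] * dg[b + radius] * v
                    sy += dg[a + radius] * g[b + radius] * v
            gx[r, c] = sx
            gy[r, c] = sy
    return gx, gy


def brute_bilinear(grid: np.ndarray, r: float, c: float) -> float:
    h, w = grid.shape
    r = min(max(r, 0.0), h - 1.0)
    c = min(max(c, 0.0), w - 1.0)
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * grid[r0, c0]
            + (1 - fr) * fc * grid[r0, c1]
            + fr * (1 - fc) * grid[r1, c0]
            + fr * fc * grid[r1, c1])


def brute_detect_maxima(modulus: np.ndarray, argument: np.ndarray,
                        sigma_px: float, floor_quantile: float):
    """Exhaustive per-pixel scan of the along-gradient maximum test."""
    h, w = modulus.shape
    margin = max(1, math.ceil(3.0 * sigma_px))
    thr = np.quantile(modulus, floor_quantile)
    points = []
    for r in range(margin, h - margin):
        for c in range(margin, w - margin):
            m = modulus[r, c]
            if not m > thr:
                continue
            dx = math.cos(argument[r, c])
            dy = math.sin(argument[r, c])
            fwd = brute_bilinear(modulus, r + dy, c + dx)
            bwd = brute_bilinear(modulus, r - dy, c - dx)
            if m >= fwd and m > bwd:
                points.append((r, c))
    return points


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 8-connected components by breadth-first flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            count += 1
            queue = [(r, c)]
            seen[r, c] = True
            while queue:
                rr, cc = queue.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w
                                and mask[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
    return count


def literal_axial_resultant(arguments) -> float:
    """F as an explicit running sum of doubled-angle unit vectors."""
    sx = 0.0
    sy = 0.0
    n = 0
    for a in arguments:
        sx += math.cos(2.0 * a)
        sy += math.sin(2.0 * a)
        n += 1
    return math.hypot(sx, sy) / n
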