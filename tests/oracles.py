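"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (double loops, explicit
index reflection, longhand ANOVA) and stays independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Mirror an out-of-range index about the array edges (edge not repeated)."""
    if n == 1:
        return 0
    period = 2 * (n - 1)
    i = abs(i) % period
    return period - i if i >= n else i


def window_filter(grid: np.ndarray, k: int, fn) -> np.ndarray:
    """Apply ``fn`` to every k x k window with mirrored borders (double loop)."""
    h = k // 2
    n_r, n_c = grid.shape
    out = np.empty((n_r, n_c), dtype=float)
    for r in range(n_r):
        for c in range(n_c):
            vals = [
                grid[reflect_index(r + dr, n_r), reflect_index(c + dc, n_c)]
                for dr in range(-h, h + 1)
                for dc in range(-h, h + 1)
            ]
            out[r, c] = fn(np.asarray(vals))
    return out


def avg_oracle(grid: np.ndarray, k: int) -> np.ndarray:
    return window_filter(grid, k, np.mean)


def std_oracle(grid: np.ndarray, k: int) -> np.ndarray:
    return window_filter(grid, k, lambda v: v.std(ddof=1))


def cascade_oracle(region: np.ndarray, gt1: float, epsilon: float = 1e-8):
    """Straight-line re-implementation of the six filter stages + gate."""
    i1 = avg_oracle(region, 7)
    i2 = std_oracle(region, 7)
    i3 = i2 / (i1 + epsilon)
    i4 = region - i3
    i5 = avg_oracle(i4, 11)
    i6 = avg_oracle(region, 9)
    i7 = np.where(i6 < gt1, 0.0, np.clip(i5, 0.0, 1.0))
    return i7


def point_in_polygon(r: float, c: float, vertices, tol: float = 1e-9) -> bool:
    """Even-odd rule with boundary points counted inside."""
    n = len(vertices)
    inside = False
    for idx in range(n):
        r1, c1 = vertices[idx]
        r2, c2 = vertices[(idx + 1) % n]
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        if (
            abs(cross) <= tol
            and min(r1, r2) - tol <= r <= max(r1, r2) + tol
            and min(c1, c2) - tol <= c <= max(c1, c2) + tol
        ):
            return True  # on the boundary
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c_cross > c:
                inside = not inside
    return inside


def rasterize_oracle(vertices, shape) -> np.ndarray:
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            mask[r, c] = point_in_polygon(float(r), float(c), vertices)
    return mask


def multiotsu_oracle(vals: np.ndarray, nbins: int) -> np.ndarray:
    """Exhaustive two-threshold Otsu search by explicit slicing."""
    hist, edges = np.histogram(vals, bins=nbins, range=(vals.min(), vals.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist / hist.sum()
    best, best_pair = -np.inf, None
    for i in range(nbins - 2):
        for j in range(i + 1, nbins - 1):
            sigma = 0.0
            for sel in (slice(0, i + 1), slice(i + 1, j + 1), slice(j + 1, nbins)):
                wk = w[sel].sum()
                if wk > 0:
                    mu = (w[sel] * centers[sel]).sum() / wk
                    sigma += wk * mu * mu
            if sigma > best:
                best, best_pair = sigma, (i, j)
    return centers[list(best_pair)]


def exact_otsu_objective(vals: np.ndarray, nbins: int, thresholds) -> "Fraction":
    """Between-class variance term (sum w_k mu_k^2) in exact rational
    arithmetic for a given threshold pair, enabling tie-free comparison."""
    from fractions import Fraction

    hist, edges = np.histogram(vals, bins=nbins, range=(vals.min(), vals.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    i = int(np.searchsorted(centers, thresholds[0]))
    j = int(np.searchsorted(centers, thresholds[1]))
    counts = [int(h) for h in hist]
    cents = [Fraction(float(c)) for c in centers]
    total = Fraction(0)
    for a, b in ((0, i + 1), (i + 1, j + 1), (j + 1, nbins)):
        wk = sum(counts[a:b])
        if wk:
            mk = sum(counts[t] * cents[t] for t in range(a, b))
            total += mk * mk / wk
    return total


def icc21_oracle(x: np.ndarray) -> float:
    """ICC(2,1) computed longhand from explicit ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (x[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (x[:, j].mean() - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def shoelace_area(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    r, c = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))
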