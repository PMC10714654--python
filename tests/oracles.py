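"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the ellipse oracle is a
brute-force geometric-distance minimizer over a refined parameter grid
(moment-based initialization, polygon-distance objective), and the
perimeter oracle is direct numerical quadrature of the arc-length integral.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def perimeter_quadrature(a: float, b: float) -> float:
    """Ellipse perimeter by numeric quadrature of the arc-length integral."""
    integrand = lambda t: np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
    val, _err = quad(integrand, 0.0, np.pi / 2.0, limit=200)
    return 4.0 * val


def _ellipse_polygon(cx, cy, a, b, angle_deg, n=180):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ang = np.deg2rad(angle_deg)
    x = cx + a * np.cos(t) * np.cos(ang) - b * np.sin(t) * np.sin(ang)
    y = cy + a * np.cos(t) * np.sin(ang) + b * np.sin(t) * np.cos(ang)
    return np.column_stack([x, y])


def _objective(points, params):
    poly = _ellipse_polygon(*params)
    d2 = ((points[:, None, :] - poly[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def _moment_init(points):
    """Centroid + principal second moments of boundary samples.

    For points sampled uniformly in the ellipse parameter, the coordinate
    covariance is R diag(a^2/2, b^2/2) R^T, so axes and orientation follow
    from its eigendecomposition.
    """
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    a, b = np.sqrt(2.0 * w[0]), np.sqrt(2.0 * w[1])
    angle = np.degrees(np.arctan2(v[1, 0], v[0, 0])) % 180.0
    return c[0], c[1], a, b, angle


def grid_search_ellipse(points, n_refine=4, n_grid=5):
    """Brute-force geometric ellipse fit: refine a 5-D parameter grid around
    the moment initialization, minimizing summed squared point-to-polygon
    distances.  Returns (cx, cy, a, b, angle_deg)."""
    points = np.asarray(points, dtype=float)
    centre = np.array(_moment_init(points))
    spans = np.array([2.0, 2.0, 3.0, 3.0, 12.0])
    best = tuple(centre)
    for _ in range(n_refine):
        axes = [np.linspace(c - s, c + s, n_grid) for c, s in zip(best, spans)]
        candidates = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 5)
        candidates = candidates[candidates[:, 2] > 0]
        candidates = candidates[candidates[:, 3] > 0]
        scores = [_objective(points, p) for p in candidates]
        best = tuple(candidates[int(np.argmin(scores))])
        spans = spans / (n_grid - 1) * 1.5  # keep neighbouring grid cells in range
    a, b, ang = best[2], best[3], best[4]
    if b > a:
        a, b, ang = b, a, ang + 90.0
    return best[0], best[1], a, b, ang % 180.0
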