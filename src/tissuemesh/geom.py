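"""Small 3D geometric predicates used across the reconstruction pipeline."""

from __future__ import annotations

import numpy as np

__all__ = [
    "tet_volume",
    "circumsphere_center",
    "circumcircle_center",
    "barycentric_coordinates",
    "closest_point_on_triangle",
    "triangle_area",
    "triangle_angles",
]


class DegenerateSimplexError(ValueError):
    """Simplex too flat for the requested construction."""


def tet_volume(pts: np.ndarray) -> float:
    """Signed volume of a tetrahedron given as a (4, 3) array."""
    p = np.asarray(pts, dtype=float)
    return float(np.linalg.det(p[1:] - p[0]) / 6.0)


def circumsphere_center(pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Centre of the sphere through 4 affinely independent points.

    Solves the linear equidistance system; raises
    :class:`DegenerateSimplexError` when the tetrahedron volume is below
    ``tol`` relative to its size.
    """
    p = np.asarray(pts, dtype=float)
    a = 2.0 * (p[1:] - p[0])
    scale = max(np.abs(a).max(), 1.0)
    if abs(np.linalg.det(a)) < tol * scale ** 3:
        raise DegenerateSimplexError("flat tetrahedron has no circumsphere")
    b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
    return np.linalg.solve(a, b)


def circumcircle_center(pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Circumcircle centre of a 3D triangle, in the triangle's plane."""
    p = np.asarray(pts, dtype=float)
    u, v = p[1] - p[0], p[2] - p[0]
    n = np.cross(u, v)
    n2 = n @ n
    if n2 < tol:
        raise DegenerateSimplexError("degenerate triangle")
    uu, vv, uv = u @ u, v @ v, u @ v
    denom = 2.0 * (uu * vv - uv * uv)
    if abs(denom) < tol:
        raise DegenerateSimplexError("degenerate triangle")
    return p[0] + (vv * (uu - uv) * u + uu * (vv - uv) * v) / denom


def barycentric_coordinates(p: np.ndarray, tet: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``p`` with respect to a tetrahedron."""
    t = np.asarray(tet, dtype=float)
    m = np.vstack([(t[1:] - t[0]).T])
    rhs = np.asarray(p, dtype=float) - t[0]
    lam = np.linalg.solve(m, rhs)
    return np.concatenate([[1.0 - lam.sum()], lam])


def triangle_area(pts: np.ndarray) -> float:
    p = np.asarray(pts, dtype=float)
    return 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))


def triangle_angles(pts: np.ndarray) -> np.ndarray:
    """Interior angles (radians) of a 3D triangle; degenerate -> zeros."""
    p = np.asarray(pts, dtype=float)
    out = np.zeros(3)
    for i in range(3):
        u = p[(i + 1) % 3] - p[i]
        v = p[(i + 2) % 3] - p[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return np.zeros(3)
        c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        out[i] = np.arccos(c)
    return out


def closest_point_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point of a 3D triangle to ``p`` (Ericson's region walk)."""
    a, b, c = (np.asarray(v, dtype=float) for v in tri)
    p = np.asarray(p, dtype=float)
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)
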