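"""Multi-criteria quality estimation of tissue meshes.

Ten normalized estimators, each in [0, 1] with 1 = ideal, covering four
aspects of what "a good tissue mesh" means:

* prior consistency — cell_convexity (cell volume over convex-hull volume),
  epidermis_cell_angle (surface junction wedge angles against the
  theoretical 120°, normalized by a 30° deviation), cell_cliques (fraction
  of junctions where no more than 4 cells — 3 on the surface — meet);
* image consistency — image_accuracy (mean per-cell Jaccard overlap between
  segmented regions and the voxelized mesh), vertex_distance (mean matched
  corner-to-image distance, as a reciprocal of the voxel diagonal at a
  typical 0.25 μm resolution), cell_2adjacency (Jaccard of the image's wall
  adjacencies and the mesh's dual adjacency edges);
* intrinsic regularity — triangle_area_deviation (area standard deviation
  against √2 × mean area), triangle_eccentricity (mean of
  1 − Σ sin(angles) / (3 sin 60°), normalized by 0.5), vertex_valence
  (mean |valence − 6| of interface-interior vertices, normalized by 6);
* complexity — mesh_complexity (triangle incidences per cell against a
  reference of 152, a good triangulation of the space-filling truncated
  octahedron).

The aggregate quality is the arithmetic mean of the ten scores, suited to a
radar ("spider-web") plot.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .draco import EXTERIOR
from .geom import triangle_angles, triangle_area
from .image_adjacency import ImageAdjacencies, SegmentedImage
from .stem import SIN60, TissueMesh, _eccentricity, _vertex_classes

__all__ = [
    "QualityReport",
    "prior_scores",
    "voxelize_mesh",
    "image_scores",
    "intrinsic_scores",
    "complexity_score",
    "quality_report",
    "tissue_properties",
    "cell_oriented_triangles",
]

SCORE_ORDER = [
    "cell_convexity", "epidermis_cell_angle", "cell_cliques",
    "image_accuracy", "vertex_distance", "cell_2adjacency",
    "triangle_area_deviation", "triangle_eccentricity", "vertex_valence",
    "mesh_complexity",
]

#: voxel diagonal at a typical 0.25 μm image resolution (μm)
DEFAULT_D0 = 0.25 * np.sqrt(3.0)
#: reference triangle count per cell
DEFAULT_COMPLEXITY_REF = 152.0
#: angular normalizer for the 120° junction estimator (degrees)
DEFAULT_ANGLE_REF = 30.0


class OpenCellError(ValueError):
    """A cell's boundary surface is not closed."""


@dataclass
class QualityReport:
    scores: Dict[str, float] = field(default_factory=dict)
    raw: Dict[str, float] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def average_quality(self) -> float:
        vals = [self.scores[k] for k in SCORE_ORDER if k in self.scores
                and self.scores[k] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def radar_data(self) -> List[Tuple[str, float]]:
        """(axis name, score) rows in the canonical plot order."""
        return [(k, self.scores.get(k)) for k in SCORE_ORDER]

    def as_dict(self) -> Dict:
        return {"scores": dict(self.scores), "raw": dict(self.raw),
                "counts": dict(self.counts),
                "average_quality": self.average_quality}


def _clamp(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


# ---------------------------------------------------------------------------
# orientation and per-cell geometry
# ---------------------------------------------------------------------------


def cell_oriented_triangles(mesh: TissueMesh, label: int) -> np.ndarray:
    """The cell's boundary triangles, wound consistently outward.

    Orientation is not stored in the mesh; it is derived on demand by
    propagating a consistent winding over the cell's closed surface and
    flipping globally if the signed volume comes out negative.
    """
    tids = mesh.cell_triangles(int(label))
    if len(tids) == 0:
        raise KeyError(f"no triangles for cell {label}")
    tris = {int(ti): tuple(int(v) for v in mesh.triangles[ti]) for ti in tids}
    edge_map: Dict[Tuple[int, int], List[int]] = defaultdict(list)
    for ti, t in tris.items():
        for i in range(3):
            u, v = t[i], t[(i + 1) % 3]
            edge_map[(min(u, v), max(u, v))].append(ti)
    if any(len(ts) != 2 for ts in edge_map.values()):
        raise OpenCellError(f"cell {label} boundary is not closed")
    oriented: Dict[int, Tuple[int, int, int]] = {}
    for seed in sorted(tris):
        if seed in oriented:
            continue
        oriented[seed] = tris[seed]
        stack = [seed]
        while stack:
            ti = stack.pop()
            t = oriented[ti]
            directed = {(t[i], t[(i + 1) % 3]) for i in range(3)}
            for i in range(3):
                u, v = t[i], t[(i + 1) % 3]
                for tj in edge_map[(min(u, v), max(u, v))]:
                    if tj == ti or tj in oriented:
                        continue
                    s = tris[tj]
                    sd = {(s[i2], s[(i2 + 1) % 3]) for i2 in range(3)}
                    # neighbour must traverse the shared edge oppositely
                    oriented[tj] = s if (v, u) in sd else (s[0], s[2], s[1])
                    stack.append(tj)
    order = sorted(oriented)
    arr = np.asarray([oriented[ti] for ti in order], dtype=np.int64)
    p = mesh.vertices
    vol = np.einsum("ij,ij->i", p[arr[:, 0]],
                    np.cross(p[arr[:, 1]], p[arr[:, 2]])).sum() / 6.0
    if vol < 0:
        arr = arr[:, [0, 2, 1]]
    return arr


def cell_volume(mesh: TissueMesh, label: int) -> float:
    """Cell volume by the divergence theorem over its closed boundary."""
    arr = cell_oriented_triangles(mesh, label)
    p = mesh.vertices
    return float(np.einsum("ij,ij->i", p[arr[:, 0]],
                           np.cross(p[arr[:, 1]], p[arr[:, 2]])).sum() / 6.0)


# ---------------------------------------------------------------------------
# prior consistency
# ---------------------------------------------------------------------------


def _surface_junction_vertices(mesh: TissueMesh):
    """Vertices where exactly >= 3 cells meet on the free surface."""
    cells = mesh.vertex_cells()
    return [(v, frozenset(x for x in s if x != EXTERIOR))
            for v, s in enumerate(cells)
            if EXTERIOR in s and len(s) >= 4]


def _wedge_angles(mesh: TissueMesh, v: int) -> Dict[int, float]:
    """Tangent-plane angular sector of each cell around a surface junction.

    The incident free-surface triangles are projected onto the junction's
    fitted tangent plane; each cell's wedge is the sum of its triangles'
    projected angles at the vertex, rescaled so the wedges close up to 360°.
    """
    tids = [ti for ti in range(mesh.n_triangles())
            if v in mesh.triangles[ti] and mesh.tri_labels[ti][0] == EXTERIOR]
    if not tids:
        return {}
    normals = []
    for ti in tids:
        p = mesh.triangle_points(ti)
        n = np.cross(p[1] - p[0], p[2] - p[0])
        nn = np.linalg.norm(n)
        if nn > 1e-15:
            normals.append(n / nn)
    if not normals:
        return {}
    n0 = normals[0]
    normals = [n if n @ n0 >= 0 else -n for n in normals]
    n = np.mean(normals, axis=0)
    n /= max(np.linalg.norm(n), 1e-15)
    wedges: Dict[int, float] = defaultdict(float)
    for ti in tids:
        tri = [int(x) for x in mesh.triangles[ti]]
        cell = int(mesh.tri_labels[ti][1])
        others = [x for x in tri if x != v]
        u1 = mesh.vertices[others[0]] - mesh.vertices[v]
        u2 = mesh.vertices[others[1]] - mesh.vertices[v]
        u1 = u1 - (u1 @ n) * n
        u2 = u2 - (u2 @ n) * n
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        ang = np.arccos(np.clip(u1 @ u2 / (n1 * n2), -1.0, 1.0))
        wedges[cell] += np.degrees(ang)
    total = sum(wedges.values())
    if total <= 0:
        return {}
    return {c: w * 360.0 / total for c, w in wedges.items()}


def prior_scores(mesh: TissueMesh,
                 angle_ref: float = DEFAULT_ANGLE_REF) -> Dict[str, float]:
    """cell_convexity, epidermis_cell_angle, cell_cliques."""
    p = mesh.vertices
    convexities = []
    for label in mesh.cell_labels():
        vol = cell_volume(mesh, int(label))  # raises OpenCellError if open
        vids = sorted({int(v) for ti in mesh.cell_triangles(int(label))
                       for v in mesh.triangles[ti]})
        try:
            hull_vol = ConvexHull(p[vids]).volume
        except Exception:
            hull_vol = abs(vol)
        convexities.append(abs(vol) / max(hull_vol, 1e-12))
    cell_convexity = float(np.mean(convexities)) if convexities else 1.0

    deviations = []
    for v, cells in _surface_junction_vertices(mesh):
        if len(cells) != 3:
            continue
        wedges = _wedge_angles(mesh, v)
        if len(wedges) != 3:
            continue
        deviations.append(np.mean([abs(w - 120.0)
                                   for w in wedges.values()]))
    if deviations:
        raw_dev = float(np.mean(deviations))
        epidermis_cell_angle = _clamp(1.0 - raw_dev / angle_ref)
    else:
        raw_dev = 0.0
        epidermis_cell_angle = 1.0

    all_cells = mesh.vertex_cells()
    junctions = 0
    bad = 0
    for s in all_cells:
        if EXTERIOR in s:
            k = len(s) - 1
            if k >= 3:
                junctions += 1
                if k > 3:
                    bad += 1
        else:
            if len(s) >= 4:
                junctions += 1
                if len(s) > 4:
                    bad += 1
    cell_cliques = 1.0 - (bad / junctions if junctions else 0.0)
    return {
        "cell_convexity": _clamp(cell_convexity),
        "epidermis_cell_angle": epidermis_cell_angle,
        "cell_cliques": _clamp(cell_cliques),
        "_raw": {"mean_convexity": cell_convexity,
                 "mean_angle_deviation_deg": raw_dev,
                 "junction_violations": bad, "junctions": junctions},
    }


# ---------------------------------------------------------------------------
# voxelization and image consistency
# ---------------------------------------------------------------------------


def voxelize_mesh(mesh: TissueMesh, image: SegmentedImage) -> SegmentedImage:
    """Rasterize the mesh cells back onto the image's voxel grid.

    Each voxel centre is assigned the label of the (watertight) cell that
    contains it, by parity ray casting along +x with a tiny symbolic
    perturbation against on-face ties; voxels in no cell get the background
    label.
    """
    shape = image.shape
    vs = np.asarray(image.voxel_size)
    out = np.full(shape, image.background_label, dtype=np.int32)
    eps = 1e-6 * min(vs)
    for label in sorted(int(l) for l in mesh.cell_labels()):
        arr = cell_oriented_triangles(mesh, label)  # raises if open
        tri_pts = mesh.vertices[arr]  # (n, 3, 3) in world (z, y, x) μm
        zmin, ymin, _ = tri_pts.min(axis=(0, 1))
        zmax, ymax, _ = tri_pts.max(axis=(0, 1))
        k0 = max(int(np.floor(zmin / vs[0] - 0.5)), 0)
        k1 = min(int(np.ceil(zmax / vs[0] - 0.5)), shape[0] - 1)
        j0 = max(int(np.floor(ymin / vs[1] - 0.5)), 0)
        j1 = min(int(np.ceil(ymax / vs[1] - 0.5)), shape[1] - 1)
        crossings: Dict[Tuple[int, int], List[float]] = defaultdict(list)
        for pts in tri_pts:
            # ray at (z, y) crosses the triangle's (z, y) projection
            tz0, ty0 = pts[:, 0].min(), pts[:, 1].min()
            tz1, ty1 = pts[:, 0].max(), pts[:, 1].max()
            ka = max(int(np.ceil(tz0 / vs[0] - 0.5)), k0)
            kb = min(int(np.floor(tz1 / vs[0] - 0.5)), k1)
            ja = max(int(np.ceil(ty0 / vs[1] - 0.5)), j0)
            jb = min(int(np.floor(ty1 / vs[1] - 0.5)), j1)
            if ka > kb or ja > jb:
                continue
            a, b, c = pts
            m = np.array([[b[0] - a[0], c[0] - a[0]],
                          [b[1] - a[1], c[1] - a[1]]])
            det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
            if abs(det) < 1e-15:
                continue
            inv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
            ks = (np.arange(ka, kb + 1) + 0.5) * vs[0] + eps
            js = (np.arange(ja, jb + 1) + 0.5) * vs[1] + eps
            zz, yy = np.meshgrid(ks, js, indexing="ij")
            rz = zz - a[0]
            ry = yy - a[1]
            lam1 = inv[0, 0] * rz + inv[0, 1] * ry
            lam2 = inv[1, 0] * rz + inv[1, 1] * ry
            inside = (lam1 >= 0) & (lam2 >= 0) & (lam1 + lam2 <= 1)
            if not inside.any():
                continue
            xs = a[2] + lam1 * (b[2] - a[2]) + lam2 * (c[2] - a[2])
            kk, jj = np.nonzero(inside)
            for ki, ji, x in zip(kk, jj, xs[inside]):
                crossings[(ka + ki, ja + ji)].append(float(x))
        for (k, j), xs in crossings.items():
            xs = sorted(xs)
            for i0 in range(0, len(xs) - 1, 2):
                ia = int(np.ceil(xs[i0] / vs[2] - 0.5 + 1e-9))
                ib = int(np.floor(xs[i0 + 1] / vs[2] - 0.5 - 1e-9))
                ia = max(ia, 0)
                ib = min(ib, shape[2] - 1)
                if ia <= ib:
                    row = out[k, j, ia:ib + 1]
                    row[row == image.background_label] = label
    return SegmentedImage(out, image.voxel_size, image.background_label)


def image_scores(mesh: TissueMesh, image: SegmentedImage,
                 adj: ImageAdjacencies,
                 d0: float = DEFAULT_D0,
                 voxelized: Optional[SegmentedImage] = None,
                 ) -> Dict[str, float]:
    """image_accuracy, vertex_distance, cell_2adjacency."""
    if voxelized is None:
        voxelized = voxelize_mesh(mesh, image)
    jaccards = []
    for label in sorted(int(l) for l in mesh.cell_labels()):
        a = image.labels == label
        b = voxelized.labels == label
        union = int(np.logical_or(a, b).sum())
        inter = int(np.logical_and(a, b).sum())
        jaccards.append(inter / union if union else 0.0)
    image_accuracy = float(np.mean(jaccards)) if jaccards else 0.0

    cells = mesh.vertex_cells()
    bg = adj.background_label
    dists = []
    for v, s in enumerate(cells):
        if EXTERIOR in s:
            if len(s) < 4:
                continue
            key = frozenset(x for x in s if x != EXTERIOR) | {bg}
        elif len(s) >= 4:
            key = frozenset(s)
        else:
            continue
        p = adj.corner_points.get(key)
        if p is None:
            continue
        dists.append(float(np.linalg.norm(mesh.vertices[v] - p)))
    if dists:
        mean_d = float(np.mean(dists))
        vertex_distance = 1.0 if mean_d <= d0 else _clamp(d0 / mean_d)
    else:
        mean_d = None
        vertex_distance = None  # undefined, reported missing

    img_edges = adj.cell_edges()
    mesh_edges = mesh.adjacency_pairs()
    union = img_edges | mesh_edges
    cell_2adjacency = len(img_edges & mesh_edges) / len(union) if union else 1.0
    return {
        "image_accuracy": _clamp(image_accuracy),
        "vertex_distance": vertex_distance,
        "cell_2adjacency": _clamp(cell_2adjacency),
        "_raw": {"mean_cell_jaccard": image_accuracy,
                 "mean_corner_distance": mean_d,
                 "matched_corners": len(dists)},
    }


# ---------------------------------------------------------------------------
# intrinsic regularity and complexity
# ---------------------------------------------------------------------------


def intrinsic_scores(mesh: TissueMesh) -> Dict[str, float]:
    """triangle_area_deviation, triangle_eccentricity, vertex_valence."""
    areas = np.array([triangle_area(mesh.triangle_points(i))
                      for i in range(mesh.n_triangles())])
    mean_area = float(areas.mean()) if len(areas) else 0.0
    std_area = float(areas.std()) if len(areas) else 0.0
    if std_area <= 1e-12 * mean_area:  # numerically identical areas
        std_area = 0.0
    triangle_area_deviation = _clamp(
        1.0 - std_area / (np.sqrt(2.0) * max(mean_area, 1e-12)))

    eccs = np.array([_eccentricity(mesh.triangle_points(i))
                     for i in range(mesh.n_triangles())])
    mean_ecc = float(eccs.mean()) if len(eccs) else 0.0
    if abs(mean_ecc) <= 1e-12:  # numerically equilateral
        mean_ecc = 0.0
    triangle_eccentricity = _clamp(1.0 - mean_ecc / 0.5)

    feature, _ = _vertex_classes(mesh)
    valence = np.zeros(mesh.n_vertices(), dtype=int)
    for (u, v) in mesh.edge_triangles():
        valence[u] += 1
        valence[v] += 1
    interior = ~feature
    if interior.any():
        mean_dev = float(np.mean(np.abs(valence[interior] - 6.0)))
    else:
        mean_dev = 0.0
    vertex_valence = _clamp(1.0 - mean_dev / 6.0)
    return {
        "triangle_area_deviation": triangle_area_deviation,
        "triangle_eccentricity": triangle_eccentricity,
        "vertex_valence": vertex_valence,
        "_raw": {"area_std": std_area, "area_mean": mean_area,
                 "mean_eccentricity": mean_ecc,
                 "mean_valence_deviation": mean_dev},
    }


def complexity_score(mesh: TissueMesh,
                     reference: float = DEFAULT_COMPLEXITY_REF,
                     ) -> Dict[str, float]:
    """mesh_complexity: triangles needed per cell, as a reciprocal score.

    Shared wall triangles count once for each of their two cells.
    """
    labels = mesh.cell_labels()
    if len(labels) == 0:
        raise ValueError("mesh has no cells")
    incidences = sum(len(mesh.cell_triangles(int(l))) for l in labels)
    per_cell = incidences / len(labels)
    return {
        "mesh_complexity": float(min(1.0, reference / max(per_cell, 1e-12))),
        "_raw": {"triangles_per_cell": per_cell},
    }


def quality_report(mesh: TissueMesh, image: SegmentedImage,
                   adj: ImageAdjacencies,
                   d0: float = DEFAULT_D0,
                   angle_ref: float = DEFAULT_ANGLE_REF,
                   complexity_ref: float = DEFAULT_COMPLEXITY_REF,
                   ) -> QualityReport:
    """Assemble the full ten-estimator report."""
    report = QualityReport()
    for part in (prior_scores(mesh, angle_ref),
                 image_scores(mesh, image, adj, d0),
                 intrinsic_scores(mesh),
                 complexity_score(mesh, complexity_ref)):
        raw = part.pop("_raw", {})
        report.raw.update(raw)
        report.scores.update(part)
    report.counts = {
        "cells": int(len(mesh.cell_labels())),
        "vertices": int(mesh.n_vertices()),
        "triangles": int(mesh.n_triangles()),
    }
    return report


# ---------------------------------------------------------------------------
# geometric property projection
# ---------------------------------------------------------------------------


def tissue_properties(mesh: TissueMesh) -> Dict[str, Dict]:
    """Cell volumes, interface areas, and surface curvature estimates.

    Returns property maps: ``cell_volume`` (label -> μm³),
    ``interface_area`` (label pair -> μm²), and per-surface-vertex
    ``gaussian_curvature`` (angle deficit over mixed area, 1/μm²),
    ``mean_curvature`` (cotangent Laplacian magnitude, 1/μm),
    ``principal_directions`` (two orthogonal tangent unit vectors,
    descending |curvature|, from a local quadric fit).
    """
    volumes = {int(l): abs(cell_volume(mesh, int(l)))
               for l in mesh.cell_labels()}
    areas: Dict[Tuple[int, int], float] = defaultdict(float)
    for ti in range(mesh.n_triangles()):
        areas[tuple(int(x) for x in mesh.tri_labels[ti])] += \
            triangle_area(mesh.triangle_points(ti))

    # free-surface submesh
    surf_tids = [ti for ti in range(mesh.n_triangles())
                 if mesh.tri_labels[ti][0] == EXTERIOR]
    ring: Dict[int, List[int]] = defaultdict(list)
    for ti in surf_tids:
        for v in mesh.triangles[ti]:
            ring[int(v)].append(ti)
    gauss: Dict[int, float] = {}
    meanc: Dict[int, float] = {}
    principal: Dict[int, np.ndarray] = {}
    p = mesh.vertices
    surf_edge_tris: Dict[Tuple[int, int], List[int]] = defaultdict(list)
    for ti in surf_tids:
        a, b, c = (int(x) for x in mesh.triangles[ti])
        for u, v in ((a, b), (b, c), (a, c)):
            surf_edge_tris[(min(u, v), max(u, v))].append(ti)
    boundary_verts = {v for e, ts in surf_edge_tris.items()
                      if len(ts) != 2 for v in e}
    for v, tids in ring.items():
        if v in boundary_verts:
            continue
        angle_sum = 0.0
        area_sum = 0.0
        for ti in tids:
            tri = [int(x) for x in mesh.triangles[ti]]
            i = tri.index(v)
            angle_sum += triangle_angles(p[tri])[i]
            area_sum += triangle_area(p[tri]) / 3.0
        if area_sum < 1e-15:
            continue
        gauss[v] = float((2.0 * np.pi - angle_sum) / area_sum)
        # cotangent mean-curvature normal
        lap = np.zeros(3)
        neighbors = set()
        for ti in tids:
            tri = [int(x) for x in mesh.triangles[ti]]
            neighbors.update(x for x in tri if x != v)
        for u in neighbors:
            e = (min(u, v), max(u, v))
            cot = 0.0
            for ti in surf_edge_tris.get(e, []):
                tri = [int(x) for x in mesh.triangles[ti]]
                wv = next(x for x in tri if x not in e)
                a1 = p[e[0]] - p[wv]
                a2 = p[e[1]] - p[wv]
                denom = np.linalg.norm(np.cross(a1, a2))
                if denom > 1e-15:
                    cot += (a1 @ a2) / denom
            lap += cot * (p[u] - p[v])
        meanc[v] = float(np.linalg.norm(lap) / (4.0 * area_sum))
        principal[v] = _principal_directions(mesh, v, sorted(neighbors))
    return {
        "cell_volume": volumes,
        "interface_area": dict(areas),
        "gaussian_curvature": gauss,
        "mean_curvature": meanc,
        "principal_directions": principal,
    }


def _principal_directions(mesh: TissueMesh, v: int,
                          neighbors: Sequence[int]) -> np.ndarray:
    """Principal curvature directions from a quadric fit of the one-ring."""
    p = mesh.vertices
    ring = p[list(neighbors)] - p[v]
    if len(ring) < 5:
        return np.full((2, 3), np.nan)
    _, _, vt = np.linalg.svd(ring, full_matrices=False)
    t1, t2, n = vt
    x = ring @ t1
    y = ring @ t2
    z = ring @ n
    A = np.stack([x * x, x * y, y * y], axis=1)
    try:
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    except np.linalg.LinAlgError:
        return np.full((2, 3), np.nan)
    a, b, c = coef
    shape_op = np.array([[2 * a, b], [b, 2 * c]])
    w, vec = np.linalg.eigh(shape_op)
    order = np.argsort(-np.abs(w))
    dirs = []
    for i in order:
        d = vec[0, i] * t1 + vec[1, i] * t2
        dirs.append(d / max(np.linalg.norm(d), 1e-15))
    return np.asarray(dirs)
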