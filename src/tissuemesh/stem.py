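"""Tissue-specific enhancement of non-manifold triangular meshes.

The polyhedral complex produced by the dual reconstruction is turned into a
triangular mesh ("star" triangulation of each cell interface) and optimized
for finite-element use while keeping the cell topology frozen: optional
pre-processing (split refinement, isotropic remeshing, surface-vertex
projection onto the tissue isosurface, cell-corner pinning to their image
positions) followed by an annealed minimization of a three-term energy of
the same form as the adjacency energy — an image-attachment term tying
vertices to the actual cell walls, a shape-prior term flattening the cell
interfaces into polygonal walls, and a regularization term for triangle
shape and vertex valence.  The only moves are vertex shifts inside a small
sphere and edge flips interior to a single interface, so the dual cell
adjacency (which cells share a wall) is preserved exactly.

A tissue mesh is non-manifold by construction: edges along cell-junction
lines carry three or more triangles (one per incident wall).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .complex_core import IncidenceComplex
from .draco import (EXTERIOR, AnnealingSchedule, EnergyBreakdown,
                    _surface_projector)
from .geom import triangle_angles, triangle_area
from .image_adjacency import SegmentedImage

logger = logging.getLogger(__name__)

__all__ = [
    "TissueMesh",
    "StemWeights",
    "star_triangulate",
    "split_refine",
    "isotropic_remesh",
    "project_surface_vertices",
    "pin_cell_corners",
    "stem_energy",
    "optimize_mesh",
]

SIN60 = np.sin(np.pi / 3.0)


@dataclass
class TissueMesh:
    """Non-manifold triangular tissue mesh.

    ``tri_labels[i]`` is the unordered cell-label pair of triangle ``i``
    (wall between two cells, or ``(0, cell)`` for the free surface,
    ``EXTERIOR = 0``).  Vertex flags mark cell corners (junction vertices of
    the polyhedral complex), surface vertices, and pinned vertices
    (immovable during optimization).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    tri_labels: np.ndarray
    is_corner: np.ndarray = None
    is_surface: np.ndarray = None
    pinned: np.ndarray = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.tri_labels = np.asarray(self.tri_labels, dtype=np.int64)
        n = len(self.vertices)
        if self.is_corner is None:
            self.is_corner = np.zeros(n, dtype=bool)
        if self.is_surface is None:
            self.is_surface = np.zeros(n, dtype=bool)
        if self.pinned is None:
            self.pinned = np.zeros(n, dtype=bool)
        self.tri_labels = np.sort(self.tri_labels, axis=1)

    # -- basic queries -----------------------------------------------------

    def copy(self) -> "TissueMesh":
        return TissueMesh(self.vertices.copy(), self.triangles.copy(),
                          self.tri_labels.copy(), self.is_corner.copy(),
                          self.is_surface.copy(), self.pinned.copy())

    def n_vertices(self) -> int:
        return len(self.vertices)

    def n_triangles(self) -> int:
        return len(self.triangles)

    def cell_labels(self) -> np.ndarray:
        labs = np.unique(self.tri_labels)
        return labs[labs != EXTERIOR]

    def interface_keys(self) -> Set[Tuple[int, int]]:
        return {tuple(p) for p in np.unique(self.tri_labels, axis=0)}

    def adjacency_pairs(self) -> Set[Tuple[int, int]]:
        """Cell pairs sharing a wall (the mesh's dual adjacency edges)."""
        return {p for p in self.interface_keys() if p[0] != EXTERIOR}

    def edge_triangles(self) -> Dict[Tuple[int, int], List[int]]:
        out: Dict[Tuple[int, int], List[int]] = defaultdict(list)
        for ti, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (a, c)):
                out[(min(u, v), max(u, v))].append(ti)
        return out

    def cell_triangles(self, label: int) -> np.ndarray:
        mask = np.any(self.tri_labels == label, axis=1)
        return np.nonzero(mask)[0]

    def watertight(self, label: int) -> bool:
        """Every edge of the cell's triangles used by exactly two of them."""
        tris = self.cell_triangles(label)
        if len(tris) == 0:
            return False
        count: Dict[Tuple[int, int], int] = defaultdict(int)
        for ti in tris:
            a, b, c = self.triangles[ti]
            for u, v in ((a, b), (b, c), (a, c)):
                count[(min(u, v), max(u, v))] += 1
        return all(c == 2 for c in count.values())

    def vertex_interfaces(self) -> List[Set[Tuple[int, int]]]:
        out: List[Set[Tuple[int, int]]] = [set() for _ in range(len(self.vertices))]
        for ti, tri in enumerate(self.triangles):
            lab = tuple(self.tri_labels[ti])
            for v in tri:
                out[v].add(lab)
        return out

    def vertex_cells(self) -> List[FrozenSet[int]]:
        """Incident cell labels per vertex (EXTERIOR included if on surface)."""
        out = [set() for _ in range(len(self.vertices))]
        for ti, tri in enumerate(self.triangles):
            a, b = self.tri_labels[ti]
            for v in tri:
                out[v].add(int(a))
                out[v].add(int(b))
        return [frozenset(s) for s in out]

    def triangle_points(self, ti: int) -> np.ndarray:
        return self.vertices[self.triangles[ti]]

    def median_edge_length(self) -> float:
        e = np.array(sorted(self.edge_triangles()))
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                           axis=1)
        return float(np.median(d))

    def to_incidence_complex(self) -> IncidenceComplex:
        """Incidence-graph view (cells > triangles > edges > vertices)."""
        C = IncidenceComplex(top_dim=3)
        for vi, p in enumerate(self.vertices):
            C.add_element(0, element_id=vi)
            C.positions[vi] = np.asarray(p, float)
        edge_ids: Dict[Tuple[int, int], int] = {}
        next_id = len(self.vertices)
        for e in sorted(self.edge_triangles()):
            eid = C.add_element(1, element_id=next_id, boundary=e)
            edge_ids[e] = eid
            next_id += 1
        tri_ids = []
        for tri in self.triangles:
            a, b, c = (int(v) for v in tri)
            bnd = [edge_ids[(min(u, v), max(u, v))]
                   for u, v in ((a, b), (b, c), (a, c))]
            tid = C.add_element(2, element_id=next_id, boundary=bnd)
            tri_ids.append(tid)
            next_id += 1
        for label in self.cell_labels():
            faces = [tri_ids[ti] for ti in self.cell_triangles(int(label))]
            cid = C.add_element(3, element_id=next_id, boundary=faces)
            C.set_property(3, "label", cid, int(label))
            next_id += 1
        for ti, tid in enumerate(tri_ids):
            C.set_property(2, "interface", tid, tuple(self.tri_labels[ti]))
        return C


def _default_stem_schedule() -> AnnealingSchedule:
    # the mesh energy is a mean over thousands of elements, so single-move
    # deltas are ~1e-4; the temperature scale must match for the Metropolis
    # rule to discriminate
    return AnnealingSchedule(t_start=1e-4, t_end=5e-6, cycles=2,
                             cooling_factor=0.7)


@dataclass
class StemWeights:
    """Weights and annealing controls for the mesh optimization."""

    w_image: float = 1.0
    w_prior: float = 0.5
    w_regularity: float = 0.5
    shift_radius: Optional[float] = None  # default: half the median edge
    volume_bound: float = 0.1  # max relative per-cell volume change
    schedule: AnnealingSchedule = field(default_factory=_default_stem_schedule)

    def __post_init__(self):
        if self.shift_radius is not None and self.shift_radius <= 0:
            raise ValueError("shift_radius must be positive")


# ---------------------------------------------------------------------------
# triangulation and refinement
# ---------------------------------------------------------------------------


def star_triangulate(cellcomplex: IncidenceComplex) -> TissueMesh:
    """Fan every polygonal interface from a new centre vertex.

    An interface with k boundary edges becomes k triangles sharing a vertex
    at the mean position of the interface's boundary vertices; interface
    labels are inherited, original vertices keep their corner/surface flags.
    """
    vmap: Dict[int, int] = {}
    verts: List[np.ndarray] = []
    is_corner: List[bool] = []
    is_surface: List[bool] = []
    surf_prop = cellcomplex.get_property(0, "is_surface")
    for vid in sorted(cellcomplex.elements(0)):
        vmap[vid] = len(verts)
        verts.append(np.asarray(cellcomplex.positions[vid], float))
        is_corner.append(True)
        is_surface.append(bool(surf_prop.get(vid, False)))
    tris: List[Tuple[int, int, int]] = []
    labels: List[Tuple[int, int]] = []
    iface_prop = cellcomplex.get_property(2, "interface")
    for fid in sorted(cellcomplex.elements(2)):
        edge_ids = cellcomplex.boundary_of(2, fid)
        if len(edge_ids) < 3:
            raise ValueError(f"interface {fid} has fewer than 3 edges")
        ring_vids = sorted({v for e in edge_ids
                            for v in cellcomplex.boundary_of(1, e)})
        center = np.mean([cellcomplex.positions[v] for v in ring_vids], axis=0)
        ci = len(verts)
        verts.append(center)
        pair = tuple(sorted(iface_prop.get(fid, (EXTERIOR, EXTERIOR))))
        is_corner.append(False)
        is_surface.append(pair[0] == EXTERIOR)
        for e in sorted(edge_ids):
            v1, v2 = sorted(cellcomplex.boundary_of(1, e))
            tris.append((ci, vmap[v1], vmap[v2]))
            labels.append(pair)
    return TissueMesh(np.asarray(verts), np.asarray(tris, dtype=np.int64),
                      np.asarray(labels, dtype=np.int64),
                      np.asarray(is_corner), np.asarray(is_surface))


def split_refine(mesh: TissueMesh, rounds: int = 1) -> TissueMesh:
    """Uniform 1-to-4 triangle subdivision with shared edge midpoints.

    Midpoints are shared across all triangles incident to an edge (including
    non-manifold junction edges), so watertightness and interface labels are
    preserved and total interface area is conserved exactly.
    """
    out = mesh.copy()
    for _ in range(rounds):
        edge_tris = out.edge_triangles()
        # an edge is on the free surface iff one of its triangles is
        surf_edge = {e: any(out.tri_labels[t][0] == EXTERIOR for t in ts)
                     for e, ts in edge_tris.items()}
        verts = list(out.vertices)
        is_corner = list(out.is_corner)
        is_surface = list(out.is_surface)
        pinned = list(out.pinned)
        mid: Dict[Tuple[int, int], int] = {}
        for e in sorted(edge_tris):
            mid[e] = len(verts)
            verts.append(0.5 * (out.vertices[e[0]] + out.vertices[e[1]]))
            is_corner.append(False)
            is_surface.append(bool(surf_edge[e]))
            pinned.append(False)
        tris: List[Tuple[int, int, int]] = []
        labels: List[Tuple[int, int]] = []
        for ti, (a, b, c) in enumerate(out.triangles):
            ab = mid[(min(a, b), max(a, b))]
            bc = mid[(min(b, c), max(b, c))]
            ca = mid[(min(c, a), max(c, a))]
            lab = tuple(out.tri_labels[ti])
            for t in ((a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)):
                tris.append(t)
                labels.append(lab)
        out = TissueMesh(np.asarray(verts), np.asarray(tris, np.int64),
                         np.asarray(labels, np.int64),
                         np.asarray(is_corner), np.asarray(is_surface),
                         np.asarray(pinned))
    return out


def _vertex_classes(mesh: TissueMesh):
    """(feature_vertex, interface_of_vertex) for remeshing constraints.

    Feature vertices — corners, pinned vertices, vertices of several
    interfaces (junction lines) and vertices on an interface's open boundary
    — are never moved or collapsed away, and are excluded from the
    interface-interior valence statistics.
    """
    iface = mesh.vertex_interfaces()
    feature = (mesh.is_corner | mesh.pinned).copy()
    for v, s in enumerate(iface):
        if len(s) > 1:
            feature[v] = True
    for e, ts in mesh.edge_triangles().items():
        if len(ts) != 2:
            feature[e[0]] = True
            feature[e[1]] = True
    return feature, iface


def isotropic_remesh(mesh: TissueMesh, target_length: float,
                     iterations: int = 4,
                     max_elements: int = 200_000) -> TissueMesh:
    """Split-long / collapse-short / flip / smooth toward a target edge length.

    The classic incremental remeshing loop, restricted so that cell topology
    is untouched: edges on interface boundaries (junction lines) and corner
    vertices are never collapsed or moved, flips stay interior to a single
    interface, and smoothing is tangential (vertices stay on their local
    interface plane).  Median edge length lands within ~25% of the target.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    area = sum(triangle_area(mesh.triangle_points(i))
               for i in range(mesh.n_triangles()))
    budget = 4.0 * area / (SIN60 * target_length ** 2)
    if budget > max_elements:
        raise ValueError(
            f"target length {target_length} implies ~{budget:.0f} triangles "
            f"(> budget {max_elements})")
    out = mesh.copy()
    hi, lo = 4.0 / 3.0 * target_length, 4.0 / 5.0 * target_length
    for _ in range(iterations):
        out = _split_long_edges(out, hi)
        out = _collapse_short_edges(out, lo, target_length)
        out = _flip_for_valence(out)
        _tangential_smooth(out)
    return out


def _split_long_edges(mesh: TissueMesh, hi: float) -> TissueMesh:
    edge_tris = mesh.edge_triangles()
    long_edges = sorted(
        e for e in edge_tris
        if np.linalg.norm(mesh.vertices[e[0]] - mesh.vertices[e[1]]) > hi)
    if not long_edges:
        return mesh
    verts = list(mesh.vertices)
    is_corner = list(mesh.is_corner)
    is_surface = list(mesh.is_surface)
    pinned = list(mesh.pinned)
    tris = [tuple(t) for t in mesh.triangles]
    labels = [tuple(l) for l in mesh.tri_labels]
    for e in long_edges:
        incident = [ti for ti, t in enumerate(tris)
                    if t is not None and e[0] in t and e[1] in t]
        if not incident:
            continue
        m = len(verts)
        verts.append(0.5 * (np.asarray(verts[e[0]]) + np.asarray(verts[e[1]])))
        is_corner.append(False)
        is_surface.append(any(labels[ti][0] == EXTERIOR for ti in incident))
        pinned.append(False)
        for ti in incident:
            a, b, c = tris[ti]
            opp = next(v for v in (a, b, c) if v not in e)
            lab = labels[ti]
            tris[ti] = None
            labels[ti] = None
            tris.append((e[0], m, opp))
            labels.append(lab)
            tris.append((m, e[1], opp))
            labels.append(lab)
    keep = [i for i, t in enumerate(tris) if t is not None]
    return TissueMesh(np.asarray(verts),
                      np.asarray([tris[i] for i in keep], np.int64),
                      np.asarray([labels[i] for i in keep], np.int64),
                      np.asarray(is_corner), np.asarray(is_surface),
                      np.asarray(pinned))


def _collapse_short_edges(mesh: TissueMesh, lo: float, target: float,
                          ) -> TissueMesh:
    feature, iface = _vertex_classes(mesh)
    edge_tris = mesh.edge_triangles()
    tris = [tuple(t) for t in mesh.triangles]
    labels = [tuple(l) for l in mesh.tri_labels]
    alias = np.arange(mesh.n_vertices())
    removed_tris: Set[int] = set()
    vertex_tris: Dict[int, Set[int]] = defaultdict(set)
    for ti, t in enumerate(tris):
        for v in t:
            vertex_tris[v].add(ti)
    hi = 4.0 / 3.0 * target

    def resolve(v):
        while alias[v] != v:
            v = alias[v]
        return v

    for e in sorted(edge_tris):
        u, v = resolve(e[0]), resolve(e[1])
        if u == v:
            continue
        d = np.linalg.norm(mesh.vertices[u] - mesh.vertices[v])
        if d >= lo:
            continue
        # collapse the free endpoint into the kept one
        if feature[u] and feature[v]:
            continue
        keep, gone = (u, v) if feature[u] else (v, u)
        ts_gone = {ti for ti in vertex_tris[gone] if ti not in removed_tris}
        ts_keep = {ti for ti in vertex_tris[keep] if ti not in removed_tris}
        shared = {ti for ti in ts_gone
                  if keep in tuple(resolve(x) for x in tris[ti])}
        # manifold link condition within the interface: the collapse must
        # remove exactly the triangles containing both endpoints (2 on a
        # manifold interior edge), and the endpoints' one-rings may only
        # meet at the two opposite vertices
        if len(shared) != 2:
            continue

        def ring(x, ts):
            r = set()
            for ti in ts:
                r.update(resolve(y) for y in tris[ti])
            r.discard(x)
            return r

        opp = set()
        for ti in shared:
            opp.update(resolve(y) for y in tris[ti])
        opp -= {u, v}
        if ring(gone, ts_gone) & ring(keep, ts_keep) != opp:
            continue
        ok = True
        for ti in ts_gone - shared:
            t = tuple(resolve(x) for x in tris[ti])
            newt = tuple(keep if x == gone else x for x in t)
            if len(set(newt)) != 3:
                ok = False
                break
            p = mesh.vertices[list(newt)]
            if triangle_area(p) < 1e-12:
                ok = False
                break
            if max(np.linalg.norm(p[i] - p[j])
                   for i in range(3) for j in range(i)) > hi:
                ok = False
                break
        if not ok:
            continue
        alias[gone] = keep
        removed_tris |= shared
        vertex_tris[keep] |= ts_gone - shared
        feature[keep] = feature[keep] or feature[gone]

    new_tris, new_labels = [], []
    for ti, t in enumerate(tris):
        if ti in removed_tris:
            continue
        rt = tuple(resolve(x) for x in t)
        if len(set(rt)) != 3:
            continue
        new_tris.append(rt)
        new_labels.append(labels[ti])
    used = sorted({v for t in new_tris for v in t})
    remap = {v: i for i, v in enumerate(used)}
    return TissueMesh(mesh.vertices[used],
                      np.asarray([[remap[v] for v in t] for t in new_tris],
                                 np.int64),
                      np.asarray(new_labels, np.int64),
                      mesh.is_corner[used], mesh.is_surface[used],
                      mesh.pinned[used])


def _flip_for_valence(mesh: TissueMesh) -> TissueMesh:
    valence = np.zeros(mesh.n_vertices(), dtype=int)
    edge_tris = mesh.edge_triangles()
    for (u, v) in edge_tris:
        valence[u] += 1
        valence[v] += 1
    feature, iface = _vertex_classes(mesh)
    tris = [list(t) for t in mesh.triangles]
    labels = mesh.tri_labels

    def target(v):
        return 4 if feature[v] else 6

    for e in sorted(edge_tris):
        ts = edge_tris.get(e)
        if ts is None or len(ts) != 2:
            continue
        t1, t2 = ts
        if tuple(labels[t1]) != tuple(labels[t2]):
            continue
        u, v = e
        o1 = next(x for x in tris[t1] if x not in e)
        o2 = next(x for x in tris[t2] if x not in e)
        if o1 == o2:
            continue
        before = sum(abs(valence[x] - target(x)) for x in (u, v, o1, o2))
        after = (abs(valence[u] - 1 - target(u)) + abs(valence[v] - 1 - target(v))
                 + abs(valence[o1] + 1 - target(o1))
                 + abs(valence[o2] + 1 - target(o2)))
        if after >= before:
            continue
        key = (min(o1, o2), max(o1, o2))
        if key in edge_tris:
            continue
        p = mesh.vertices
        a1 = triangle_area(p[[u, o1, o2]])
        a2 = triangle_area(p[[v, o1, o2]])
        if a1 < 1e-12 or a2 < 1e-12:
            continue
        n1 = np.cross(p[o1] - p[u], p[o2] - p[u])
        n2 = np.cross(p[o2] - p[v], p[o1] - p[v])
        if n1 @ n2 <= 0:  # folded configuration
            continue
        tris[t1] = [u, o1, o2]
        tris[t2] = [v, o2, o1]
        del edge_tris[e]
        edge_tris[key] = [t1, t2]
        # rim edges keep their keys but swap triangle owners
        for rim, lose, gain in (((min(v, o1), max(v, o1)), t1, t2),
                                ((min(u, o2), max(u, o2)), t2, t1)):
            lst = edge_tris[rim]
            lst[lst.index(lose)] = gain
        valence[u] -= 1
        valence[v] -= 1
        valence[o1] += 1
        valence[o2] += 1
    return TissueMesh(mesh.vertices.copy(), np.asarray(tris, np.int64),
                      labels.copy(), mesh.is_corner.copy(),
                      mesh.is_surface.copy(), mesh.pinned.copy())


def _tangential_smooth(mesh: TissueMesh, lam: float = 0.5) -> None:
    """Laplacian smoothing of interface-interior vertices, restricted to the
    local interface plane (in place)."""
    feature, iface = _vertex_classes(mesh)
    neighbors: Dict[int, Set[int]] = defaultdict(set)
    for (u, v) in mesh.edge_triangles():
        neighbors[u].add(v)
        neighbors[v].add(u)
    new = mesh.vertices.copy()
    for v in range(mesh.n_vertices()):
        if feature[v] or mesh.pinned[v] or not neighbors[v]:
            continue
        ring = np.asarray([mesh.vertices[u] for u in sorted(neighbors[v])])
        centroid = ring.mean(axis=0)
        d = centroid - mesh.vertices[v]
        # project the move onto the local plane (one-ring normal)
        ctr = ring - ring.mean(axis=0)
        _, _, vt = np.linalg.svd(ctr, full_matrices=False)
        n = vt[2]
        d = d - (d @ n) * n
        new[v] = mesh.vertices[v] + lam * d
    mesh.vertices[:] = new


# ---------------------------------------------------------------------------
# image attachment
# ---------------------------------------------------------------------------


def project_surface_vertices(mesh: TissueMesh, isosurface) -> TissueMesh:
    """Move every surface-flagged vertex to its nearest isosurface point."""
    out = mesh.copy()
    project = _surface_projector(isosurface)
    for v in np.nonzero(out.is_surface)[0]:
        out.vertices[v] = project(out.vertices[v])
    return out


def pin_cell_corners(mesh: TissueMesh,
                     corner_points: Dict[FrozenSet[int], np.ndarray],
                     tolerance: float = np.inf,
                     background_label: int = 1) -> TissueMesh:
    """Snap junction vertices to the cell-corner positions of the image.

    A mesh vertex incident to >= 4 cells (>= 3 plus the exterior on the
    surface) is matched to the image corner with the same incident label set
    (the exterior standing in for the background); matched vertices move to
    the image point and become pinned.  If two mesh vertices match one
    corner, the nearest is kept; unmatched corners are logged.
    """
    out = mesh.copy()
    cells = out.vertex_cells()
    matches: Dict[FrozenSet[int], List[int]] = defaultdict(list)
    for v in range(out.n_vertices()):
        s = cells[v]
        if EXTERIOR in s:
            if len(s) >= 4:  # 3 cells + exterior
                key = frozenset(x for x in s if x != EXTERIOR) | \
                    {background_label}
                matches[key].append(v)
        elif len(s) >= 4:
            matches[frozenset(s)].append(v)
    n_matched = 0
    for key, vs in sorted(matches.items(), key=lambda kv: sorted(kv[0])):
        if key not in corner_points:
            logger.debug("mesh corner %s has no image corner", set(key))
            continue
        p = np.asarray(corner_points[key], float)
        vs = sorted(vs, key=lambda v: np.linalg.norm(out.vertices[v] - p))
        v = vs[0]
        if np.linalg.norm(out.vertices[v] - p) > tolerance:
            continue
        out.vertices[v] = p
        out.pinned[v] = True
        n_matched += 1
        for other in vs[1:]:
            logger.debug("corner %s: extra mesh vertex %d left unpinned",
                         set(key), other)
    logger.info("pinned %d cell corners", n_matched)
    return out


def _wall_point_trees(image: SegmentedImage):
    """KD-trees of inter-label wall points (face midpoints), per label pair.

    The ``(background, cell)`` pairs describe the free surface.
    """
    lab = image.labels
    vs = np.asarray(image.voxel_size)
    clouds: Dict[Tuple[int, int], List[np.ndarray]] = defaultdict(list)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = lab[tuple(sl_a)]
        b = lab[tuple(sl_b)]
        diff = np.argwhere(a != b)
        la = a[tuple(diff.T)]
        lb = b[tuple(diff.T)]
        mid = (diff + 0.5) * vs
        mid[:, axis] += 0.5 * vs[axis]
        lo = np.minimum(la, lb)
        hi = np.maximum(la, lb)
        for pair in np.unique(np.stack([lo, hi], 1), axis=0):
            m = (lo == pair[0]) & (hi == pair[1])
            clouds[(int(pair[0]), int(pair[1]))].append(mid[m])
    return {k: cKDTree(np.vstack(v)) for k, v in clouds.items()}


def _interface_to_image_pair(pair: Tuple[int, int], bg: int) -> Tuple[int, int]:
    a, b = pair
    if a == EXTERIOR:
        a = bg
    return (min(a, b), max(a, b))


def stem_energy(mesh: TissueMesh, image: SegmentedImage,
                w: StemWeights = None,
                _trees=None) -> EnergyBreakdown:
    """Three-term mesh energy against the segmented image.

    ``e_image``: mean over non-pinned vertices of the squared distance (μm²)
    to the nearest inter-label wall point compatible with the vertex's
    incident interfaces (averaged over its interfaces).  ``e_prior``: mean
    over interfaces of the mean squared vertex distance to the interface's
    best-fit plane (flat polygonal walls).  ``e_regularity``: mean triangle
    eccentricity plus mean squared (valence − 6) over interface-interior
    vertices.
    """
    if w is None:
        w = StemWeights()
    state = _MeshState(mesh, image, trees=_trees)
    return state.energy(w)


class _MeshState:
    """Incremental bookkeeping of the mesh energy for the optimizer.

    All three terms are kept as running sums so a proposal is scored in
    O(local patch): per-vertex image distances, per-interface flatness,
    per-triangle eccentricity, per-vertex valence.
    """

    def __init__(self, mesh: TissueMesh, image: SegmentedImage, trees=None):
        self.mesh = mesh
        self.image = image
        self.trees = trees if trees is not None else _wall_point_trees(image)
        self.bg = image.background_label
        # squared-distance terms are made dimensionless by the voxel
        # diagonal, so the three weights act on comparable scales
        self.scale2 = float(np.sum(np.asarray(image.voxel_size) ** 2))
        self.vert_iface = mesh.vertex_interfaces()
        self.feature, _ = _vertex_classes(mesh)

        self.iface_verts: Dict[Tuple[int, int], Set[int]] = defaultdict(set)
        for ti, tri in enumerate(mesh.triangles):
            key = tuple(mesh.tri_labels[ti])
            for v in tri:
                self.iface_verts[key].add(int(v))

        self.active = ~mesh.pinned
        self.v_img = np.zeros(mesh.n_vertices())
        for v in range(mesh.n_vertices()):
            self.v_img[v] = self._image_term(v)
        self.sum_img = float(self.v_img[self.active].sum())
        self.n_active = int(self.active.sum())

        self.iface_flat: Dict[Tuple[int, int], float] = {}
        for key in self.iface_verts:
            self.iface_flat[key] = self._flatness(key)
        self.sum_flat = float(sum(self.iface_flat.values()))
        self.n_iface = len(self.iface_flat)

        self.tri_ecc = np.array([_eccentricity(mesh.triangle_points(i))
                                 for i in range(mesh.n_triangles())])
        self.sum_ecc = float(self.tri_ecc.sum())
        self.n_tri = mesh.n_triangles()

        self.valence = np.zeros(mesh.n_vertices(), dtype=int)
        self.edge_tris = mesh.edge_triangles()
        for (u, v) in self.edge_tris:
            self.valence[u] += 1
            self.valence[v] += 1
        self.interior = ~self.feature & ~mesh.pinned
        self.sum_valsq = float(((self.valence[self.interior] - 6.0) ** 2).sum())
        self.n_interior = int(self.interior.sum())

        self.vtris: Dict[int, Set[int]] = defaultdict(set)
        for ti, tri in enumerate(mesh.triangles):
            for v in tri:
                self.vtris[int(v)].add(ti)
        self._init_volumes()

    def _tri_det(self, ti) -> float:
        a, b, c = self.mesh.vertices[self.mesh.triangles[ti]]
        return float(a @ np.cross(b, c)) / 6.0

    def _init_volumes(self):
        """Per-cell signed volumes with per-(triangle, cell) outward signs,
        so vertex shifts can be volume-checked incrementally."""
        from .quality import cell_oriented_triangles
        mesh = self.mesh
        self.tri_sign: Dict[Tuple[int, int], float] = {}
        self.cell_vol: Dict[int, float] = {}
        self.cell_vol0: Dict[int, float] = {}
        self.tri_det = np.array([self._tri_det(ti)
                                 for ti in range(mesh.n_triangles())])
        tids_of_cell = {int(l): mesh.cell_triangles(int(l))
                        for l in mesh.cell_labels()}
        for label, tids in tids_of_cell.items():
            try:
                arr = cell_oriented_triangles(mesh, label)
            except Exception:
                continue
            stored = {ti: tuple(int(x) for x in mesh.triangles[ti])
                      for ti in tids}
            vol = 0.0
            for ti, oriented in zip(sorted(stored), arr):
                t = stored[ti]
                ot = tuple(int(x) for x in oriented)
                sign = 1.0 if ot in (t, t[1:] + t[:1], t[2:] + t[:2]) else -1.0
                self.tri_sign[(ti, label)] = sign
                vol += sign * self.tri_det[ti]
            self.cell_vol[label] = vol
            self.cell_vol0[label] = abs(vol)

    def volume_ok(self, touched_tris, label_pairs, bound) -> bool:
        """Check the per-cell volume bound after updating ``tri_det`` for the
        touched triangles (call with dets already refreshed)."""
        cells = {int(c) for pair in label_pairs for c in pair if c != 0}
        for c in cells:
            if c not in self.cell_vol0 or self.cell_vol0[c] < 1e-12:
                continue
            if abs(abs(self.cell_vol[c]) - self.cell_vol0[c]) \
                    > bound * self.cell_vol0[c]:
                return False
        return True

    def _image_term(self, v: int) -> float:
        total, n = 0.0, 0
        p = self.mesh.vertices[v]
        for pair in self.vert_iface[v]:
            key = _interface_to_image_pair(pair, self.bg)
            tree = self.trees.get(key)
            if tree is None:
                continue
            d, _ = tree.query(p)
            total += d * d
            n += 1
        return total / n if n else 0.0

    def _flatness(self, key) -> float:
        vs = sorted(self.iface_verts[key])
        if len(vs) < 4:
            return 0.0
        pts = self.mesh.vertices[vs]
        ctr = pts - pts.mean(axis=0)
        # smallest eigenvalue of the 3x3 covariance = sum of squared
        # distances to the best-fit plane
        cov = ctr.T @ ctr
        return float(np.linalg.eigvalsh(cov)[0] / len(vs))

    def energy(self, w: StemWeights) -> EnergyBreakdown:
        e_image = self.sum_img / (self.n_active * self.scale2) \
            if self.n_active else 0.0
        e_prior = self.sum_flat / (self.n_iface * self.scale2) \
            if self.n_iface else 0.0
        ecc = self.sum_ecc / self.n_tri if self.n_tri else 0.0
        val = self.sum_valsq / self.n_interior if self.n_interior else 0.0
        e_reg = ecc + val
        total = w.w_image * e_image + w.w_prior * e_prior \
            + w.w_regularity * e_reg
        return EnergyBreakdown(e_image, e_prior, e_reg, total)


def _eccentricity(pts: np.ndarray) -> float:
    """1 − (sin α + sin β + sin γ) / (3 sin 60°): 0 equilateral, 1 degenerate."""
    s = float(np.sin(triangle_angles(pts)).sum())
    return 1.0 - s / (3.0 * SIN60)


def optimize_mesh(mesh: TissueMesh, image: SegmentedImage,
                  w: StemWeights = None,
                  isosurface=None) -> TissueMesh:
    """Annealed minimization of the mesh energy.

    Moves: random displacement of a non-pinned vertex inside a sphere of
    ``shift_radius`` (surface vertices are re-projected onto the tissue
    isosurface after the shift; the radius shrinks by 0.9 per temperature
    cycle) and edge flips interior to a single interface (never across
    interfaces, so cell topology and the dual adjacency are untouched).
    Metropolis acceptance on the annealing schedule, then a zero-temperature
    quench; the best state encountered is returned, with an ``energy_log``
    attribute like the adjacency optimizer's.
    """
    if w is None:
        w = StemWeights()
    from .image_adjacency import binary_isosurface
    if isosurface is None and mesh.is_surface.any():
        isosurface = binary_isosurface(image)
    project = _surface_projector(isosurface) if isosurface is not None \
        else (lambda p: p)
    out = mesh.copy()
    adjacency_before = mesh.adjacency_pairs()
    trees = _wall_point_trees(image)
    state = _MeshState(out, image, trees=trees)
    sched = w.schedule
    rng = np.random.default_rng(sched.rng_seed)
    radius = w.shift_radius or 0.5 * out.median_edge_length()
    energy = state.energy(w).total
    best = (energy, out.vertices.copy(), out.triangles.copy())
    vol0_orig = dict(state.cell_vol0)
    movable = np.nonzero(~out.pinned)[0]
    if len(movable) == 0:
        out.energy_log = [(0, 0, 0.0, energy)]
        return out
    edge_list = sorted(state.edge_tris)
    log: List[Tuple[int, int, float, float]] = []

    def _wall_target(v):
        """Mean of the nearest compatible wall points of the vertex."""
        p = out.vertices[v]
        targets = []
        for pair in state.vert_iface[v]:
            tree = state.trees.get(_interface_to_image_pair(pair, state.bg))
            if tree is None:
                continue
            _, i = tree.query(p)
            targets.append(tree.data[i])
        return np.mean(targets, axis=0) if targets else None

    def try_shift(temperature, radius):
        nonlocal energy, best
        v = int(movable[rng.integers(len(movable))])
        old = out.vertices[v].copy()
        if rng.uniform() < 0.5:
            # directed proposal: walk toward the image walls
            tgt = _wall_target(v)
            if tgt is None:
                return
            d = tgt - old
            dist = np.linalg.norm(d)
            if dist < 1e-12:
                return
            step = d * min(1.0, radius / dist) * rng.uniform(0.5, 1.0)
        else:
            step = rng.normal(size=3)
            step *= radius * rng.uniform() ** (1 / 3) / \
                max(np.linalg.norm(step), 1e-12)
        newp = old + step
        if out.is_surface[v]:
            newp = np.asarray(project(newp), float)
        out.vertices[v] = newp
        old_img = state.v_img[v]
        new_img = state._image_term(v)
        state.v_img[v] = new_img
        if state.active[v]:
            state.sum_img += new_img - old_img
        touched = state.vert_iface[v]
        old_flat = {k: state.iface_flat[k] for k in touched}
        for k in touched:
            nf = state._flatness(k)
            state.sum_flat += nf - state.iface_flat[k]
            state.iface_flat[k] = nf
        tids = sorted(state.vtris[v])
        old_ecc = state.tri_ecc[tids].copy()
        for ti in tids:
            ne = _eccentricity(out.triangle_points(ti))
            state.sum_ecc += ne - state.tri_ecc[ti]
            state.tri_ecc[ti] = ne
        old_det = state.tri_det[tids].copy()
        dvol: Dict[int, float] = defaultdict(float)
        for ti in tids:
            nd = state._tri_det(ti)
            for c in out.tri_labels[ti]:
                c = int(c)
                sign = state.tri_sign.get((ti, c))
                if sign is not None:
                    dvol[c] += sign * (nd - state.tri_det[ti])
            state.tri_det[ti] = nd
        for c, d in dvol.items():
            state.cell_vol[c] += d
        vol_ok = all(
            abs(abs(state.cell_vol[c]) - state.cell_vol0[c])
            <= w.volume_bound * state.cell_vol0[c]
            for c in dvol if state.cell_vol0.get(c, 0.0) > 1e-12)
        new_energy = state.energy(w).total
        delta = new_energy - energy
        if vol_ok and (delta <= 0 or (temperature > 0 and rng.uniform()
                                      < np.exp(-delta / temperature))):
            energy = new_energy
            if energy < best[0] - 1e-15:
                best = (energy, out.vertices.copy(), out.triangles.copy())
        else:
            out.vertices[v] = old
            state.v_img[v] = old_img
            if state.active[v]:
                state.sum_img -= new_img - old_img
            for k, val in old_flat.items():
                state.sum_flat += val - state.iface_flat[k]
                state.iface_flat[k] = val
            for ti, oe in zip(tids, old_ecc):
                state.sum_ecc += oe - state.tri_ecc[ti]
                state.tri_ecc[ti] = oe
            for ti, od in zip(tids, old_det):
                state.tri_det[ti] = od
            for c, d in dvol.items():
                state.cell_vol[c] -= d

    def _valsq_delta(x, dv):
        if not state.interior[x]:
            return 0.0
        old = (state.valence[x] - 6.0) ** 2
        new = (state.valence[x] + dv - 6.0) ** 2
        return new - old

    def try_flip(temperature):
        nonlocal energy, best
        e = edge_list[rng.integers(len(edge_list))]
        ts = state.edge_tris.get(e)
        if not ts or len(ts) != 2:
            return
        t1, t2 = ts
        if tuple(out.tri_labels[t1]) != tuple(out.tri_labels[t2]):
            return
        u, v = e
        o1 = next((int(x) for x in out.triangles[t1] if x not in e), None)
        o2 = next((int(x) for x in out.triangles[t2] if x not in e), None)
        if o1 is None or o2 is None or o1 == o2:
            return
        key = (min(o1, o2), max(o1, o2))
        if key in state.edge_tris:
            return
        p = out.vertices
        a1 = triangle_area(p[[u, o1, o2]])
        a2 = triangle_area(p[[v, o1, o2]])
        if a1 < 1e-10 or a2 < 1e-10:
            return
        # consistently wound across the new edge, the two new triangles of a
        # valid flip have aligned normals; a fold makes them anti-parallel
        n1 = np.cross(p[o1] - p[u], p[o2] - p[u])
        n2 = np.cross(p[o2] - p[v], p[o1] - p[v])
        if n1 @ n2 <= 0:
            return
        old_t1, old_t2 = out.triangles[t1].copy(), out.triangles[t2].copy()
        # outward reference normals per cell before the flip
        pcell = [int(c) for c in out.tri_labels[t1] if c != 0]
        pts1 = out.vertices[old_t1]
        pts2 = out.vertices[old_t2]
        n1_old = np.cross(pts1[1] - pts1[0], pts1[2] - pts1[0])
        n2_old = np.cross(pts2[1] - pts2[0], pts2[2] - pts2[0])
        refs = {}
        for c in pcell:
            s1 = state.tri_sign.get((t1, c))
            s2 = state.tri_sign.get((t2, c))
            if s1 is None or s2 is None:
                return
            refs[c] = s1 * n1_old + s2 * n2_old
        out.triangles[t1] = (u, o1, o2)
        out.triangles[t2] = (v, o2, o1)
        new_signs = {}
        for c in pcell:
            sn1 = float(np.sign(n1 @ refs[c]))
            sn2 = float(np.sign(n2 @ refs[c]))
            if sn1 == 0 or sn2 == 0:
                out.triangles[t1] = old_t1
                out.triangles[t2] = old_t2
                return
            new_signs[(t1, c)] = sn1
            new_signs[(t2, c)] = sn2
        old_ecc = state.tri_ecc[[t1, t2]].copy()
        d_ecc = 0.0
        for ti in (t1, t2):
            ne = _eccentricity(out.triangle_points(ti))
            d_ecc += ne - state.tri_ecc[ti]
            state.tri_ecc[ti] = ne
        state.sum_ecc += d_ecc
        old_det = state.tri_det[[t1, t2]].copy()
        old_signs = {(ti, c): state.tri_sign.get((ti, c))
                     for ti in (t1, t2) for c in pcell}
        dvol = defaultdict(float)
        for ti, od in zip((t1, t2), old_det):
            nd = state._tri_det(ti)
            for c in pcell:
                dvol[c] += new_signs[(ti, c)] * nd - \
                    old_signs[(ti, c)] * od
            state.tri_det[ti] = nd
        for c, d in dvol.items():
            state.cell_vol[c] += d
        for k2, v2 in new_signs.items():
            state.tri_sign[k2] = v2
        vol_ok = all(
            abs(abs(state.cell_vol[c]) - state.cell_vol0[c])
            <= w.volume_bound * state.cell_vol0[c]
            for c in dvol if state.cell_vol0.get(c, 0.0) > 1e-12)
        d_val = (_valsq_delta(u, -1) + _valsq_delta(v, -1)
                 + _valsq_delta(o1, +1) + _valsq_delta(o2, +1))
        state.sum_valsq += d_val
        state.valence[u] -= 1
        state.valence[v] -= 1
        state.valence[o1] += 1
        state.valence[o2] += 1
        new_energy = state.energy(w).total
        delta = new_energy - energy
        if vol_ok and (delta <= 0 or (temperature > 0 and rng.uniform()
                                      < np.exp(-delta / temperature))):
            energy = new_energy
            del state.edge_tris[e]
            state.edge_tris[key] = [t1, t2]
            edge_list.append(key)
            # the four rim edges keep their keys but may swap triangles:
            # (v,o1) moves from t1 to t2'; (u,o2) moves from t2 to t1'
            for rim, lose, gain in (((min(v, o1), max(v, o1)), t1, t2),
                                    ((min(u, o2), max(u, o2)), t2, t1)):
                lst = state.edge_tris[rim]
                lst[lst.index(lose)] = gain
            state.vtris[v].discard(t1)
            state.vtris[o2].add(t1)
            state.vtris[u].discard(t2)
            state.vtris[o1].add(t2)
            if energy < best[0] - 1e-15:
                best = (energy, out.vertices.copy(), out.triangles.copy())
        else:
            out.triangles[t1] = old_t1
            out.triangles[t2] = old_t2
            state.sum_ecc -= d_ecc
            state.tri_ecc[[t1, t2]] = old_ecc
            state.sum_valsq -= d_val
            state.valence[u] += 1
            state.valence[v] += 1
            state.valence[o1] -= 1
            state.valence[o2] -= 1
            state.tri_det[[t1, t2]] = old_det
            for c, d in dvol.items():
                state.cell_vol[c] -= d
            for k2, v2 in old_signs.items():
                state.tri_sign[k2] = v2

    sweep_len = sched.steps_per_cycle or max(out.n_vertices(), 1)
    r = radius
    for cycle in range(sched.cycles):
        t = sched.t_start
        sweep = 0
        while t > sched.t_end:
            for _ in range(sweep_len):
                if rng.uniform() < 0.8:
                    try_shift(t, r)
                else:
                    try_flip(t)
            log.append((cycle, sweep, t, energy))
            t *= sched.cooling_factor
            sweep += 1
        r *= 0.9

    # quench from the best state
    out.vertices[:] = best[1]
    out.triangles[:] = best[2]
    state = _MeshState(out, image, trees=trees)
    state.cell_vol0 = vol0_orig  # the volume bound is against the input mesh
    energy = state.energy(w).total
    best = (energy, out.vertices.copy(), out.triangles.copy())
    edge_list = sorted(state.edge_tris)
    for sweep in range(12):
        e_before = energy
        for _ in range(sweep_len):
            try_shift(0.0, r)
        log.append((sched.cycles, sweep, 0.0, energy))
        if e_before - energy < 1e-5 * max(abs(e_before), 1e-12):
            break

    assert out.adjacency_pairs() == adjacency_before
    out.energy_log = log
    return out
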