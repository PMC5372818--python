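"""Dual reconstruction by adjacency-complex optimization.

The tissue's geometry is recovered through its dual: a simplicial complex of
cell adjacencies whose tetrahedra are quadruples of mutually adjacent cells.
The Delaunay tetrahedrization of the cell barycenters is a valid starting
point, but real tissue is locally anisotropic and the Delaunay criterion
links cells that are not actually neighbours.  The complex is therefore

1. cleaned of exterior artifacts (tetrahedra crossing the tissue surface,
   over-long edges, slivers),
2. optimized by simulated annealing over local topological moves (2-3/3-2
   bistellar flips and edge removals with cavity re-tetrahedrization),
   minimizing a three-term energy

       E(T, S) = w_image·E_image(T, S) + w_prior·E_prior(T)
                 + w_regularity·E_regularity(T)

   where ``E_image`` penalizes the symmetric difference between the complex's
   edge set and the wall adjacencies extracted from the segmented image S,
   ``E_prior`` penalizes implausible neighbour counts, and ``E_regularity``
   penalizes elongated tetrahedra, and
3. dualized into a polyhedral cell complex whose vertices sit at the
   (constrained) circumsphere centres of the adjacency tetrahedra — for an
   unmodified Delaunay complex this is exactly the Voronoi diagram of the
   barycenters — with exterior interfaces clipped to the tissue's binary
   isosurface.

A layered variant reconstructs only the outer L1/L2 cell layers by greedy
best-first aggregation of image-extracted tetrahedra, exploiting the fact
that the epidermal and subepidermal layers are anticlinally separated.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from heapq import heappush, heappop
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from . import complex_core as cc
from .complex_core import IncidenceComplex, simplicial_from_tetrahedra, simplex_labels
from .geom import (DegenerateSimplexError, barycentric_coordinates,
                   circumcircle_center, circumsphere_center,
                   closest_point_on_triangle, tet_volume)
from .image_adjacency import ImageAdjacencies, SegmentedImage

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyWeights",
    "AnnealingSchedule",
    "EnergyBreakdown",
    "delaunay_adjacency",
    "clean_exterior",
    "adjacency_energy",
    "optimize_adjacency",
    "circumsphere_center",
    "constrain_into_tetrahedron",
    "dual_geometry",
    "layer_tetra_weight",
    "aggregate_layer_complex",
]

EXTERIOR = 0  # interface label standing for "outside the tissue"

#: expected neighbour count of an interior plant cell (empirical mean for
#: meristematic tissue); surface cells are excluded from the prior
DEFAULT_NEIGHBOR_TARGET = 13.2


@dataclass
class EnergyWeights:
    """Weights of the three energy terms (all >= 0, not all zero)."""

    w_image: float = 1.0
    w_prior: float = 0.1
    w_regularity: float = 0.1

    def __post_init__(self):
        if min(self.w_image, self.w_prior, self.w_regularity) < 0:
            raise ValueError("energy weights must be nonnegative")


@dataclass
class AnnealingSchedule:
    """Temperature cycles for the simulated-annealing optimization.

    Each cycle cools geometrically from ``t_start`` to ``t_end``
    (``cooling_factor`` per sweep); high temperatures allow non-optimal
    transformations so non-trivial optima can be reached as the temperature
    lowers.  A final zero-temperature quench sweep (greedy) follows the
    cycles, and the best state encountered is returned, so the final energy
    never exceeds the initial one.
    """

    t_start: float = 1.0
    t_end: float = 0.01
    cycles: int = 3
    steps_per_cycle: int = 0  # 0 -> one proposed move per tetrahedron per sweep
    cooling_factor: float = 0.95
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.t_start > self.t_end > 0):
            raise ValueError("need t_start > t_end > 0")
        if self.cycles < 1:
            raise ValueError("need at least one cycle")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must be in (0, 1)")


@dataclass
class EnergyBreakdown:
    e_image: float
    e_prior: float
    e_regularity: float
    total: float


def delaunay_adjacency(barycenters: Dict[int, np.ndarray]) -> IncidenceComplex:
    """Delaunay tetrahedrization of the cell centres as an adjacency complex.

    Vertices are the cell labels at their barycenter positions; tetrahedra
    are the Delaunay tetrahedra.  Raises on fewer than 4 points or coplanar
    input.
    """
    labels = sorted(barycenters)
    if len(labels) < 4:
        raise ValueError("Delaunay tetrahedrization needs at least 4 points")
    pts = np.asarray([barycenters[l] for l in labels], dtype=float)
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # QhullError on degenerate input
        raise ValueError(f"degenerate barycenter set: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("coplanar barycenters admit no tetrahedrization")
    tets = {tuple(sorted(labels[v] for v in s)) for s in tri.simplices}
    return simplicial_from_tetrahedra(tets, positions=barycenters)


# ---------------------------------------------------------------------------
# tetrahedron-set state with incremental energy bookkeeping
# ---------------------------------------------------------------------------


class _TetState:
    """Mutable tetrahedron-set view of an adjacency complex.

    Tracks pair/triangle multiplicities, vertex degrees and the three energy
    terms incrementally, so a proposed patch (remove + add tetrahedra) can be
    scored and applied in O(patch size).
    """

    def __init__(self, tets: Iterable[Tuple[int, ...]],
                 positions: Dict[int, np.ndarray],
                 target_edges: Set[Tuple[int, int]],
                 interior_cells: Set[int],
                 neighbor_target: float = DEFAULT_NEIGHBOR_TARGET):
        self.positions = {k: np.asarray(v, float) for k, v in positions.items()}
        self.target_edges = {tuple(sorted(e)) for e in target_edges}
        self.interior_cells = set(interior_cells)
        self.neighbor_target = neighbor_target
        self.tets: Set[Tuple[int, ...]] = set()
        self.pair_count: Dict[Tuple[int, int], int] = defaultdict(int)
        self.tri_count: Dict[Tuple[int, int, int], int] = defaultdict(int)
        self.vert_count: Dict[int, int] = defaultdict(int)
        self.elong: Dict[Tuple[int, ...], float] = {}
        self._mismatch = len(self.target_edges)  # edges present in neither
        # running Σ (degree − target)² over interior cells, seeded at the
        # all-degrees-zero value so increments telescope correctly
        self._prior_sq = len(self.interior_cells) * self.neighbor_target ** 2
        self._degree: Dict[int, int] = defaultdict(int)
        self._elong_sum = 0.0
        for t in tets:
            self._apply_add(tuple(sorted(t)))

    # -- elementary bookkeeping -------------------------------------------

    def _pair_on(self, pair):
        if pair in self.target_edges:
            self._mismatch -= 1
        else:
            self._mismatch += 1
        for v, o in (pair, pair[::-1]):
            if v in self.interior_cells:
                d = self._degree[v]
                self._prior_sq += (d + 1 - self.neighbor_target) ** 2 - \
                    (d - self.neighbor_target) ** 2
            self._degree[v] += 1

    def _pair_off(self, pair):
        if pair in self.target_edges:
            self._mismatch += 1
        else:
            self._mismatch -= 1
        for v, o in (pair, pair[::-1]):
            if v in self.interior_cells:
                d = self._degree[v]
                self._prior_sq += (d - 1 - self.neighbor_target) ** 2 - \
                    (d - self.neighbor_target) ** 2
            self._degree[v] -= 1

    def _elongation(self, tet):
        p = np.asarray([self.positions[v] for v in tet])
        d = [np.linalg.norm(p[i] - p[j]) for i, j in combinations(range(4), 2)]
        return max(d) / max(min(d), 1e-12) - 1.0

    def _apply_add(self, tet):
        self.tets.add(tet)
        self.vert_count[tet[0]] += 1
        for v in tet[1:]:
            self.vert_count[v] += 1
        for pair in combinations(tet, 2):
            if self.pair_count[pair] == 0:
                self._pair_on(pair)
            self.pair_count[pair] += 1
        for tri in combinations(tet, 3):
            self.tri_count[tri] += 1
        e = self._elongation(tet)
        self.elong[tet] = e
        self._elong_sum += e

    def _apply_remove(self, tet):
        self.tets.remove(tet)
        for v in tet:
            self.vert_count[v] -= 1
        for pair in combinations(tet, 2):
            self.pair_count[pair] -= 1
            if self.pair_count[pair] == 0:
                self._pair_off(pair)
        for tri in combinations(tet, 3):
            self.tri_count[tri] -= 1
        self._elong_sum -= self.elong.pop(tet)

    def apply(self, remove, add):
        for t in remove:
            self._apply_remove(t)
        for t in add:
            self._apply_add(t)

    # -- queries -----------------------------------------------------------

    def edges(self) -> Set[Tuple[int, int]]:
        return {p for p, c in self.pair_count.items() if c > 0}

    def energy(self, w: EnergyWeights) -> EnergyBreakdown:
        n_target = max(len(self.target_edges), 1)
        e_image = self._mismatch / n_target
        n_int = max(len(self.interior_cells), 1)
        e_prior = (self._prior_sq / n_int) / self.neighbor_target ** 2 \
            if self.interior_cells else 0.0
        e_reg = self._elong_sum / max(len(self.tets), 1)
        total = (w.w_image * e_image + w.w_prior * e_prior
                 + w.w_regularity * e_reg)
        return EnergyBreakdown(e_image, e_prior, e_reg, total)

    def total_energy(self, w: EnergyWeights) -> float:
        return self.energy(w).total

    def valid_patch(self, remove: Sequence, add: Sequence) -> bool:
        """Structural + geometric admissibility of a proposed move.

        Checks: added tetrahedra are new and non-degenerate, no triangle
        ends up shared by more than two tetrahedra, no vertex loses its last
        tetrahedron, and the re-tetrahedrized cavity fills exactly the same
        volume it vacates (rejects overlapping or gapped configurations).
        """
        rem = set(remove)
        for t in add:
            if len(set(t)) != 4 or (t in self.tets and t not in rem):
                return False
        delta_tri = defaultdict(int)
        for t in rem:
            for tri in combinations(t, 3):
                delta_tri[tri] -= 1
        vol_rem = sum(abs(tet_volume([self.positions[v] for v in t]))
                      for t in rem)
        vol_add = 0.0
        for t in add:
            for tri in combinations(t, 3):
                delta_tri[tri] += 1
            v = abs(tet_volume([self.positions[p] for p in t]))
            if v < 1e-12:
                return False
            vol_add += v
        for tri, d in delta_tri.items():
            if self.tri_count[tri] + d > 2 or self.tri_count[tri] + d < 0:
                return False
        delta_vert = defaultdict(int)
        for t in rem:
            for v in t:
                delta_vert[v] -= 1
        for t in add:
            for v in t:
                delta_vert[v] += 1
        for v, d in delta_vert.items():
            if self.vert_count[v] + d <= 0:
                return False
        scale = max(vol_rem, vol_add, 1e-12)
        return abs(vol_rem - vol_add) <= 1e-6 * scale


def _complex_to_state(T: IncidenceComplex, adj: ImageAdjacencies,
                      neighbor_target: float = DEFAULT_NEIGHBOR_TARGET,
                      ) -> _TetState:
    tets = simplex_labels(T, 3)
    positions = dict(T.positions)
    for v in {u for t in tets for u in t}:
        if v not in positions:
            positions[v] = adj.barycenters[v]
        if v not in adj.barycenters:
            raise KeyError(f"complex vertex {v} is not an image cell")
    interior = {c for c in positions if c not in adj.surface_cells}
    return _TetState(tets, positions, adj.cell_edges(), interior,
                     neighbor_target)


def adjacency_energy(T: IncidenceComplex, adj: ImageAdjacencies,
                     w: EnergyWeights = EnergyWeights(),
                     neighbor_target: float = DEFAULT_NEIGHBOR_TARGET,
                     ) -> EnergyBreakdown:
    """Three-term energy of an adjacency complex against image adjacencies.

    ``e_image``: |edges(T) Δ walls(S)| / |walls(S)| — the symmetric
    difference between complex edges and image wall adjacencies.
    ``e_prior``: mean squared relative deviation of interior-cell neighbour
    counts from the target (surface cells are excluded — their neighbourhood
    is truncated by the background).  ``e_regularity``: mean tetrahedron
    elongation, max edge / min edge − 1.
    """
    return _complex_to_state(T, adj, neighbor_target).energy(w)


# ---------------------------------------------------------------------------
# exterior cleaning
# ---------------------------------------------------------------------------


def _min_dihedral_deg(p: np.ndarray) -> float:
    """Smallest dihedral angle of a tetrahedron, in degrees.

    At each edge, project the two opposite vertices onto the plane normal to
    the edge; the angle between the projections is the dihedral angle.
    """
    worst = 180.0
    for i, j in combinations(range(4), 2):
        c, d = (k for k in range(4) if k not in (i, j))
        u = p[j] - p[i]
        nu = np.linalg.norm(u)
        if nu < 1e-15:
            return 0.0
        u = u / nu
        vc = (p[c] - p[i]) - ((p[c] - p[i]) @ u) * u
        vd = (p[d] - p[i]) - ((p[d] - p[i]) @ u) * u
        nc, nd = np.linalg.norm(vc), np.linalg.norm(vd)
        if nc < 1e-15 or nd < 1e-15:
            return 0.0
        ang = np.degrees(np.arccos(np.clip(vc @ vd / (nc * nd), -1.0, 1.0)))
        worst = min(worst, ang)
    return worst


def _radius_edge_ratio(p: np.ndarray) -> float:
    try:
        c = circumsphere_center(p)
    except DegenerateSimplexError:
        return np.inf
    r = np.linalg.norm(p[0] - c)
    shortest = min(np.linalg.norm(p[i] - p[j])
                   for i, j in combinations(range(4), 2))
    return r / max(shortest, 1e-12)


def _segment_crosses_background(a: np.ndarray, b: np.ndarray,
                                image: SegmentedImage) -> bool:
    vs = np.asarray(image.voxel_size)
    length = np.linalg.norm((b - a) / vs)
    n = max(int(np.ceil(length * 2)), 2)
    ts = np.linspace(0.0, 1.0, n + 1)[1:-1]
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    idx = np.floor(pts / vs).astype(int)
    shp = image.labels.shape
    idx = np.clip(idx, 0, np.asarray(shp) - 1)
    vals = image.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return bool(np.any(vals == image.background_label))


def clean_exterior(T: IncidenceComplex, adj: ImageAdjacencies,
                   max_edge_factor: float = 3.0,
                   sliver_min_dihedral_deg: float = 5.0,
                   sliver_radius_edge: float = 4.0,
                   image: Optional[SegmentedImage] = None) -> IncidenceComplex:
    """Iteratively strip exterior artifacts off a Delaunay complex.

    The convex hull of the barycenters covers concavities of the tissue with
    "tent" tetrahedra that have no image support.  Boundary tetrahedra (those
    with a face not shared by two tetrahedra) are removed when they (a) link
    two cells that share no wall in the image while the segment between their
    barycenters passes through background (surface crossing), (b) contain an
    edge longer than ``max_edge_factor`` times the initial median edge
    length, or (c) are slivers (minimal dihedral angle or radius-edge ratio
    beyond threshold).  Repeats until stable.  When no image is supplied the
    surface-crossing test falls back to "both cells on the tissue surface
    and no shared wall".
    """
    state = _complex_to_state(T, adj)
    positions = state.positions
    edge_lengths = [np.linalg.norm(positions[a] - positions[b])
                    for a, b in state.edges()]
    median_edge = float(np.median(edge_lengths))
    max_len = max_edge_factor * median_edge

    def crosses_surface(tet) -> bool:
        for a, b in combinations(tet, 2):
            if adj.has_wall(a, b):
                continue
            pa, pb = positions[a], positions[b]
            if image is not None:
                if _segment_crosses_background(pa, pb, image):
                    return True
            else:
                if a in adj.surface_cells and b in adj.surface_cells:
                    return True
        return False

    changed = True
    while changed:
        changed = False
        boundary_tets = [t for t in sorted(state.tets)
                         if any(state.tri_count[tri] == 1
                                for tri in combinations(t, 3))]
        for t in boundary_tets:
            if t not in state.tets:
                continue
            if not any(state.tri_count[tri] == 1
                       for tri in combinations(t, 3)):
                continue
            p = np.asarray([positions[v] for v in t])
            long_edge = any(np.linalg.norm(positions[a] - positions[b]) > max_len
                            for a, b in combinations(t, 2))
            sliver = (_min_dihedral_deg(p) < sliver_min_dihedral_deg
                      or _radius_edge_ratio(p) > sliver_radius_edge)
            if long_edge or sliver or crosses_surface(t):
                state._apply_remove(t)
                changed = True
    if not state.tets:
        raise ValueError("exterior cleaning removed every tetrahedron")
    out = simplicial_from_tetrahedra(sorted(state.tets), positions=positions)
    return out


# ---------------------------------------------------------------------------
# simulated-annealing topological optimization
# ---------------------------------------------------------------------------


def _flip23(state: _TetState, tri: Tuple[int, int, int]):
    """Triangle swap: two tets sharing ``tri`` -> three around a new edge."""
    owners = [t for t in state.tets if set(tri) <= set(t)]
    if len(owners) != 2:
        return None
    d = next(v for v in owners[0] if v not in tri)
    e = next(v for v in owners[1] if v not in tri)
    if d == e:
        return None
    a, b, c = tri
    add = [tuple(sorted((a, b, d, e))), tuple(sorted((a, c, d, e))),
           tuple(sorted((b, c, d, e)))]
    return owners, add


def _edge_ring(state: _TetState, edge: Tuple[int, int]):
    """Ordered link ring of an interior edge, or None if open/irregular."""
    a, b = edge
    owners = [t for t in state.tets if a in t and b in t]
    if len(owners) < 3:
        return None
    ring_adj = defaultdict(list)
    for t in owners:
        u, v = (x for x in t if x not in edge)
        ring_adj[u].append(v)
        ring_adj[v].append(u)
    if any(len(vs) != 2 for vs in ring_adj.values()):
        return None
    start = min(ring_adj)
    ring = [start]
    prev, cur = None, start
    while True:
        nxts = [v for v in ring_adj[cur] if v != prev]
        if not nxts:
            return None
        prev, cur = cur, nxts[0]
        if cur == start:
            break
        ring.append(cur)
        if len(ring) > len(owners):
            return None
    if len(ring) != len(owners):
        return None
    return owners, ring


def _edge_removal(state: _TetState, edge: Tuple[int, int], apex_choice: int):
    """Remove an interior edge by fan re-tetrahedrizing its link ring."""
    found = _edge_ring(state, edge)
    if found is None:
        return None
    owners, ring = found
    k = len(ring)
    apex = ring[apex_choice % k]
    i0 = ring.index(apex)
    ring = ring[i0:] + ring[:i0]
    a, b = edge
    add = []
    for i in range(1, k - 1):
        u, v = ring[i], ring[i + 1]
        add.append(tuple(sorted((apex, u, v, a))))
        add.append(tuple(sorted((apex, u, v, b))))
    return owners, add


def optimize_adjacency(T: IncidenceComplex, adj: ImageAdjacencies,
                       w: EnergyWeights = EnergyWeights(),
                       schedule: AnnealingSchedule = AnnealingSchedule(),
                       neighbor_target: float = DEFAULT_NEIGHBOR_TARGET,
                       ) -> IncidenceComplex:
    """Anneal the adjacency complex toward the image adjacencies.

    Local moves are 2-3 bistellar flips (triangle swaps, creating an edge)
    and edge removals with fan re-tetrahedrization of the link ring (the 3-2
    flip is the ring-size-3 case).  Proposals preferentially target edges
    disagreeing with the image (absent walls to remove, missing walls to
    create), falling back to uniform moves; every move is filtered through
    structural and cavity-volume validity, so the complex is valid at every
    accepted step.  Acceptance is the Metropolis rule on the schedule's
    temperature cycles, followed by a zero-temperature quench from the best
    state encountered; the returned complex therefore never has higher
    energy than the input.  Deterministic for a fixed ``rng_seed``.

    The returned complex carries an ``energy_log`` attribute: a list of
    ``(cycle, sweep, temperature, total_energy)`` rows for the accepted
    state at the end of every sweep.
    """
    state = _complex_to_state(T, adj, neighbor_target)
    rng = np.random.default_rng(schedule.rng_seed)
    energy = state.total_energy(w)
    best_tets = set(state.tets)
    best_energy = energy
    log: List[Tuple[int, int, float, float]] = []

    def propose(temperature):
        nonlocal energy
        edges_now = state.edges()
        wrong = sorted(e for e in edges_now if e not in state.target_edges)
        missing = sorted(e for e in state.target_edges if e not in edges_now)
        move = None
        u = rng.uniform()
        if wrong and u < 0.4:
            edge = wrong[rng.integers(len(wrong))]
            move = _edge_removal(state, edge, int(rng.integers(8)))
        elif missing and u < 0.7:
            # a 2-3 flip on a shared interior triangle of the two cells'
            # tetrahedra creates the missing edge
            d, e = missing[rng.integers(len(missing))]
            tets_d = [t for t in state.tets if d in t]
            cands = []
            for t in tets_d:
                tri = tuple(x for x in t if x != d)
                others = [o for o in state.tets
                          if set(tri) <= set(o) and o != t]
                if len(others) == 1 and e in others[0]:
                    cands.append(tri)
            if cands:
                cands.sort()
                move = _flip23(state, cands[rng.integers(len(cands))])
        if move is None:
            tris = sorted(t for t, c in state.tri_count.items() if c == 2)
            if not tris:
                return
            if rng.uniform() < 0.5:
                move = _flip23(state, tris[rng.integers(len(tris))])
            else:
                pairs = sorted(state.edges())
                move = _edge_removal(state, pairs[rng.integers(len(pairs))],
                                     int(rng.integers(8)))
        if move is None:
            return
        remove, add = move
        if not state.valid_patch(remove, add):
            return
        state.apply(remove, add)
        new_energy = state.total_energy(w)
        delta = new_energy - energy
        accept = delta <= 0 or (temperature > 0 and
                                rng.uniform() < np.exp(-delta / temperature))
        if accept:
            energy = new_energy
        else:
            state.apply(add, remove)

    sweep_len = schedule.steps_per_cycle or max(len(state.tets), 1)
    for cycle in range(schedule.cycles):
        t = schedule.t_start
        sweep = 0
        while t > schedule.t_end:
            for _ in range(sweep_len):
                propose(t)
                if energy < best_energy - 1e-12:
                    best_energy = energy
                    best_tets = set(state.tets)
            log.append((cycle, sweep, t, energy))
            t *= schedule.cooling_factor
            sweep += 1

    # quench: greedy descent from the best state encountered
    state = _TetState(best_tets, state.positions, state.target_edges,
                      state.interior_cells, state.neighbor_target)
    energy = state.total_energy(w)
    for _ in range(2):
        for _ in range(sweep_len):
            propose(0.0)
        log.append((schedule.cycles, 0, 0.0, energy))

    out = simplicial_from_tetrahedra(sorted(state.tets),
                                     positions=state.positions)
    out.energy_log = log
    return out


# ---------------------------------------------------------------------------
# geometry of the dual
# ---------------------------------------------------------------------------


def constrain_into_tetrahedron(p: np.ndarray, tet: np.ndarray,
                               margin: float = 0.05) -> np.ndarray:
    """Project a point into a tetrahedron shrunk by a barycentric margin.

    Dual vertices are placed at circumsphere centres; when the local
    Delaunay property is violated the centre can leave its tetrahedron and
    create face intersections in the dual, so it is pulled back to the
    nearest point of the (slightly shrunk) tetrahedron.
    """
    tet = np.asarray(tet, dtype=float)
    lam = barycentric_coordinates(p, tet)
    if np.all(lam >= margin - 1e-12):
        return np.asarray(p, dtype=float)
    # {all barycentric coords >= margin} is the tetrahedron scaled about its
    # centroid by (1 - 4·margin)
    centroid = tet.mean(axis=0)
    shrunk = (1.0 - 4.0 * margin) * tet + 4.0 * margin * centroid
    best, best_d = None, np.inf
    for tri in combinations(range(4), 3):
        q = closest_point_on_triangle(p, shrunk[list(tri)])
        d = np.linalg.norm(q - np.asarray(p, float))
        if d < best_d:
            best, best_d = q, d
    return best


def _surface_projector(isosurface):
    """Nearest-point-on-surface function from (vertices, triangles)."""
    verts, tris = isosurface
    verts = np.asarray(verts, float)
    tris = np.asarray(tris, int)
    centroids = verts[tris].mean(axis=1)
    tree = cKDTree(centroids)

    def project(p):
        _, idx = tree.query(p, k=min(12, len(tris)))
        best, best_d = None, np.inf
        for i in np.atleast_1d(idx):
            q = closest_point_on_triangle(p, verts[tris[i]])
            d = np.linalg.norm(q - p)
            if d < best_d:
                best, best_d = q, d
        return best

    return project


def dual_geometry(T: IncidenceComplex, adj: ImageAdjacencies,
                  isosurface=None, margin: float = 0.05) -> IncidenceComplex:
    """Clipped geometric dual of an adjacency complex.

    Every adjacency tetrahedron becomes a cell-corner vertex at its
    (constrained) circumsphere centre; the constraint is applied only where
    the local empty-circumsphere property is violated, so the dual of an
    unmodified Delaunay complex is exactly the Voronoi diagram of the
    barycenters.  Boundary triangles (dual to infinite cell interfaces)
    spawn surface vertices at their circumcircle centres, projected onto the
    tissue's binary isosurface when one is supplied.  Faces are the dual
    polygons of adjacency edges, closed through the surface; each surface
    cell additionally receives its exterior cap faces.  The result is a
    polyhedral complex whose 3-cells are the tissue cells, every one of them
    watertight.

    Face property ``interface`` holds the unordered cell-label pair (with
    ``0`` for the exterior); vertex properties ``cells`` (incident cell
    labels), ``is_surface`` and ``kind`` support triangulation and quality
    estimation downstream.
    """
    tets = sorted(simplex_labels(T, 3))
    if not tets:
        raise ValueError("empty adjacency complex")
    positions = dict(T.positions)
    pts = {v: np.asarray(positions[v], float)
           for v in {u for t in tets for u in t}}

    tri_owners: Dict[Tuple[int, int, int], List[Tuple[int, ...]]] = \
        defaultdict(list)
    for t in tets:
        for tri in combinations(t, 3):
            tri_owners[tri].append(t)
    boundary_tris = sorted(tri for tri, o in tri_owners.items()
                           if len(o) == 1)

    # circumsphere centres, constrained where local Delaunay fails
    tet_center: Dict[Tuple[int, ...], np.ndarray] = {}
    for t in tets:
        p = np.asarray([pts[v] for v in t])
        try:
            c = circumsphere_center(p)
        except DegenerateSimplexError:
            logger.warning("degenerate tetrahedron %s: centroid fallback", t)
            tet_center[t] = p.mean(axis=0)
            continue
        r = np.linalg.norm(p[0] - c)
        locally_delaunay = True
        for tri in combinations(t, 3):
            for o in tri_owners[tri]:
                if o is t or o == t:
                    continue
                apex = next(v for v in o if v not in tri)
                if np.linalg.norm(pts[apex] - c) < r * (1 - 1e-9):
                    locally_delaunay = False
                    break
            if not locally_delaunay:
                break
        tet_center[t] = c if locally_delaunay \
            else constrain_into_tetrahedron(c, p, margin)

    project = _surface_projector(isosurface) if isosurface is not None \
        else (lambda p: p)
    btri_center: Dict[Tuple[int, int, int], np.ndarray] = {}
    for tri in boundary_tris:
        p = np.asarray([pts[v] for v in tri])
        try:
            c = circumcircle_center(p)
        except DegenerateSimplexError:
            c = p.mean(axis=0)
        # keep the raw centre inside the triangle's bounding region before
        # projecting: a far circumcentre of an obtuse triangle is meaningless
        lam = barycentric_coordinates_tri(c, p)
        if np.any(lam < 0):
            c = closest_point_on_triangle(c, p)
        btri_center[tri] = np.asarray(project(c), float)

    D = IncidenceComplex(top_dim=3)
    vid_of_tet: Dict[Tuple[int, ...], int] = {}
    vid_of_btri: Dict[Tuple[int, int, int], int] = {}
    for t in tets:
        vid = D.add_element(0)
        D.positions[vid] = tet_center[t]
        D.set_property(0, "cells", vid, frozenset(t))
        D.set_property(0, "is_surface", vid, False)
        D.set_property(0, "kind", vid, "corner")
        vid_of_tet[t] = vid
    for tri in boundary_tris:
        vid = D.add_element(0)
        D.positions[vid] = btri_center[tri]
        D.set_property(0, "cells", vid, frozenset(tri) | {EXTERIOR})
        D.set_property(0, "is_surface", vid, True)
        D.set_property(0, "kind", vid, "surface-corner")
        vid_of_btri[tri] = vid

    # dual edges: one per interior triangle (tet-tet), one per boundary
    # triangle (tet-surface), one per boundary edge (surface arc)
    eid_of_tri: Dict[Tuple[int, int, int], int] = {}
    for tri, owners in sorted(tri_owners.items()):
        if len(owners) == 2:
            eid = D.add_element(1, boundary=[vid_of_tet[owners[0]],
                                            vid_of_tet[owners[1]]])
        else:
            eid = D.add_element(1, boundary=[vid_of_tet[owners[0]],
                                            vid_of_btri[tri]])
        eid_of_tri[tri] = eid

    # boundary edges of the adjacency complex and their boundary triangles
    bedge_btris: Dict[Tuple[int, int], List[Tuple[int, int, int]]] = \
        defaultdict(list)
    for tri in boundary_tris:
        for pair in combinations(tri, 2):
            bedge_btris[pair].append(tri)
    eid_of_arc: Dict[Tuple[Tuple[int, int, int], Tuple[int, int, int]], int] = {}
    arc_of_bedge: Dict[Tuple[int, int], List[Tuple]] = defaultdict(list)
    for pair, btris in sorted(bedge_btris.items()):
        if len(btris) % 2 != 0:
            raise cc.ComplexError(
                f"boundary edge {pair} has {len(btris)} boundary triangles")
        # pair up boundary triangles around this edge by chain structure
        chains = _edge_face_chains(pair, tri_owners, btris)
        for t1, t2 in chains:
            key = (min(t1, t2), max(t1, t2))
            if key in eid_of_arc:
                continue
            if t1 == t2:
                raise cc.ComplexError(
                    f"degenerate surface arc at boundary edge {pair}")
            eid = D.add_element(1, boundary=[vid_of_btri[t1],
                                            vid_of_btri[t2]])
            eid_of_arc[key] = eid
            arc_of_bedge[pair].append(key)

    # faces: dual polygons of adjacency edges
    face_ids_of_pair: Dict[Tuple[int, int], List[int]] = defaultdict(list)
    all_pairs = sorted({pair for t in tets for pair in combinations(t, 2)})
    for pair in all_pairs:
        tris_here = sorted(tri for tri in tri_owners
                           if set(pair) <= set(tri))
        edge_ids = [eid_of_tri[tri] for tri in tris_here]
        edge_ids += [eid_of_arc[k] for k in arc_of_bedge.get(pair, [])]
        for cycle_edges in _edge_cycles(D, edge_ids):
            fid = D.add_element(2, boundary=cycle_edges)
            D.set_property(2, "interface", fid, tuple(sorted(pair)))
            face_ids_of_pair[pair].append(fid)

    # exterior caps: per surface cell, cycles of surface arcs
    cap_ids_of_cell: Dict[int, List[int]] = defaultdict(list)
    cells = sorted({v for t in tets for v in t})
    for cell in cells:
        arc_ids = [eid for pair, keys in arc_of_bedge.items()
                   if cell in pair for eid in (eid_of_arc[k] for k in keys)]
        if not arc_ids:
            continue
        for cycle_edges in _edge_cycles(D, arc_ids):
            fid = D.add_element(2, boundary=cycle_edges)
            D.set_property(2, "interface", fid, (EXTERIOR, cell))
            cap_ids_of_cell[cell].append(fid)

    # 3-cells: one per tissue cell, bounded by its interface + cap faces
    for cell in cells:
        faces = []
        for pair, fids in face_ids_of_pair.items():
            if cell in pair:
                faces.extend(fids)
        faces.extend(cap_ids_of_cell.get(cell, []))
        cid = D.add_element(3, boundary=faces)
        D.set_property(3, "label", cid, cell)
    return D


def barycentric_coordinates_tri(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of the in-plane projection of ``p``."""
    a, b, c = (np.asarray(v, float) for v in tri)
    u, v = b - a, c - a
    n = np.cross(u, v)
    n2 = n @ n
    if n2 < 1e-18:
        return np.array([1.0, 0.0, 0.0])
    w = np.asarray(p, float) - a
    lam2 = np.cross(w, v) @ n / n2
    lam3 = np.cross(u, w) @ n / n2
    return np.array([1.0 - lam2 - lam3, lam2, lam3])


def _edge_face_chains(pair, tri_owners, btris):
    """Pair up the boundary triangles around a boundary adjacency edge.

    The tetrahedra containing the edge form one or more open fans, each
    capped by two boundary triangles; each fan contributes one surface arc.
    """
    owners = sorted({t for tri in tri_owners if set(pair) <= set(tri)
                     for t in tri_owners[tri]})
    # adjacency between tets through shared (pair)-triangles
    tet_links = defaultdict(set)
    tri_list = [tri for tri in tri_owners if set(pair) <= set(tri)]
    for tri in tri_list:
        o = tri_owners[tri]
        if len(o) == 2:
            tet_links[o[0]].add(o[1])
            tet_links[o[1]].add(o[0])
    unvisited = set(owners)
    chains = []
    while unvisited:
        start = min(unvisited)
        comp = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt in tet_links[cur]:
                if nxt in comp:
                    continue
                comp.add(nxt)
                stack.append(nxt)
        unvisited -= comp
        caps = sorted(tri for tri in btris
                      if tri_owners[tri][0] in comp)
        if len(caps) == 2:
            chains.append((caps[0], caps[1]))
        elif len(caps) != 0:
            raise cc.ComplexError(
                f"irregular boundary fan at edge {pair}: {len(caps)} caps")
    return chains


def _edge_cycles(D: IncidenceComplex, edge_ids: List[int]) -> List[List[int]]:
    """Decompose a set of dual edges into closed vertex cycles."""
    incident = defaultdict(list)
    for eid in edge_ids:
        for vid in D.boundary_of(1, eid):
            incident[vid].append(eid)
    for vid, eids in incident.items():
        if len(eids) != 2:
            raise cc.ComplexError(
                f"dual face construction: vertex {vid} has {len(eids)} "
                f"incident edges (expected 2)")
    cycles = []
    unused = set(edge_ids)
    while unused:
        e0 = min(unused)
        cycle = [e0]
        unused.discard(e0)
        v_start, v_cur = sorted(D.boundary_of(1, e0))[:2]
        while v_cur != v_start:
            nxt = next(e for e in incident[v_cur] if e in unused)
            cycle.append(nxt)
            unused.discard(nxt)
            v_cur = next(v for v in D.boundary_of(1, nxt) if v != v_cur)
        if len(cycle) < 3:
            raise cc.ComplexError("degenerate dual face (cycle of < 3 edges)")
        cycles.append(cycle)
    return cycles


# ---------------------------------------------------------------------------
# layered reconstruction
# ---------------------------------------------------------------------------


def layer_tetra_weight(tet: Sequence[int], adj: ImageAdjacencies) -> float:
    """Image support of a candidate adjacency simplex.

    Sum over the label pairs of wall area divided by barycenter distance —
    large shared walls between nearby cells are strong evidence.  A simplex
    containing any pair that shares no wall has zero weight.
    """
    labels = sorted(tet)
    total = 0.0
    for a, b in combinations(labels, 2):
        wall = adj.wall_areas.get(frozenset((a, b)), 0.0)
        if wall <= 0.0:
            return 0.0
        d = np.linalg.norm(adj.barycenters[a] - adj.barycenters[b])
        total += wall / max(d, 1e-9)
    return total


def _tets_intersect(t1, t2, pts) -> bool:
    """Conservative geometric intersection test for two label tetrahedra."""
    shared = set(t1) & set(t2)
    p1 = np.asarray([pts[v] for v in t1])
    p2 = np.asarray([pts[v] for v in t2])

    def inside(p, tet_pts):
        lam = barycentric_coordinates(p, tet_pts)
        return np.all(lam > 1e-9)

    for v in set(t1) - shared:
        if inside(pts[v], p2):
            return True
    for v in set(t2) - shared:
        if inside(pts[v], p1):
            return True
    # edge-face crossings between non-shared simplex parts
    for a, b in combinations(t1, 2):
        if {a, b} <= shared:
            continue
        for tri in combinations(t2, 3):
            if {a, b} & (set(tri) | shared) == {a, b}:
                continue
            if _segment_hits_triangle(pts[a], pts[b],
                                      np.asarray([pts[v] for v in tri]),
                                      exclude=shared & set(tri)):
                return True
    return False


def _segment_hits_triangle(a, b, tri, exclude=frozenset()) -> bool:
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    nn = np.linalg.norm(n)
    if nn < 1e-15:
        return False
    n = n / nn
    da = (a - tri[0]) @ n
    db = (b - tri[0]) @ n
    if da * db > -1e-12:
        return False
    t = da / (da - db)
    p = a + t * (b - a)
    lam = barycentric_coordinates_tri(p, tri)
    return bool(np.all(lam > 1e-7))


def aggregate_layer_complex(adj: ImageAdjacencies,
                            mode: str = "L1L2") -> IncidenceComplex:
    """Greedy best-first aggregation of image-extracted layer simplices.

    ``L1L2``: builds a single layer of tetrahedra between the epidermal (L1)
    and subepidermal (L2) cells; valid compositions are 3 L1 + 1 L2,
    1 L1 + 3 L2, or 2 + 2, reflecting the anticlinal separation of the two
    layers.  ``L1``: builds the triangulated adjacency surface of the L1
    cells alone (dualizes to a 2.5D polygonal mesh).

    Aggregation starts from the highest-weight candidate and repeatedly adds
    the best-weighted neighbouring simplex that creates no geometric
    intersection (in the barycentric embedding) and no non-manifold face;
    ties break by lexicographic label order.
    """
    layers = adj.layers or {}
    l1 = {c for c, l in layers.items() if l == "L1"}
    l2 = {c for c, l in layers.items() if l == "L2"}
    pts = adj.barycenters

    if mode == "L1L2":
        cands = []
        for quad in adj.tetrahedra:
            labs = tuple(sorted(quad))
            n1 = sum(1 for v in labs if v in l1)
            n2 = sum(1 for v in labs if v in l2)
            if n1 + n2 != 4 or n1 == 0 or n2 == 0:
                continue
            wt = layer_tetra_weight(labs, adj)
            if wt > 0:
                cands.append((labs, wt))
    elif mode in ("L1", "L1-surface"):
        cands = []
        for tri in adj.triangles:
            labs = tuple(sorted(tri))
            if not set(labs) <= l1:
                continue
            wt = 0.0
            ok = True
            for a, b in combinations(labs, 2):
                wall = adj.wall_areas.get(frozenset((a, b)), 0.0)
                if wall <= 0:
                    ok = False
                    break
                wt += wall / max(np.linalg.norm(pts[a] - pts[b]), 1e-9)
            if ok:
                cands.append((labs, wt))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not cands:
        raise ValueError(f"no candidate simplices for mode {mode!r}")

    weight = dict(cands)
    k = 4 if mode == "L1L2" else 3
    face_of = lambda s: combinations(s, k - 1)
    by_face = defaultdict(list)
    for labs, _ in cands:
        for f in face_of(labs):
            by_face[f].append(labs)

    accepted: List[Tuple[int, ...]] = []
    face_use: Dict[Tuple[int, ...], int] = defaultdict(int)
    heap = []
    start = max(cands, key=lambda c: (c[1], [-x for x in c[0]]))[0]
    heappush(heap, (-weight[start], start))
    queued = {start}
    while heap:
        negw, labs = heappop(heap)
        if any(face_use[f] >= 2 for f in face_of(labs)):
            continue
        if mode == "L1L2":
            clash = any(_tets_intersect(labs, other, pts)
                        for other in accepted)
        else:
            clash = any(_tris_intersect(labs, other, pts)
                        for other in accepted)
        if clash:
            continue
        accepted.append(labs)
        for f in face_of(labs):
            face_use[f] += 1
        for f in face_of(labs):
            for nxt in by_face[f]:
                if nxt not in queued:
                    queued.add(nxt)
                    heappush(heap, (-weight[nxt], nxt))
    if not accepted:
        raise ValueError("aggregation accepted no simplex")
    if mode == "L1L2":
        return simplicial_from_tetrahedra(accepted, positions=pts)
    return simplicial_from_tetrahedra((), positions=pts, triangles=accepted)


def _tris_intersect(t1, t2, pts) -> bool:
    shared = set(t1) & set(t2)
    p2 = np.asarray([pts[v] for v in t2])
    for a, b in combinations(t1, 2):
        if {a, b} <= shared:
            continue
        if _segment_hits_triangle(pts[a], pts[b], p2):
            return True
    p1 = np.asarray([pts[v] for v in t1])
    for a, b in combinations(t2, 2):
        if {a, b} <= shared:
            continue
        if _segment_hits_triangle(pts[a], pts[b], p1):
            return True
    return False
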