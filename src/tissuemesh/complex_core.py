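"""Dimension-graded incidence graphs for cellular and simplicial complexes.

A cellular complex of top dimension N (here N <= 3) is stored as an incidence
graph: nodes are the n-cells (vertices, edges, faces, volumes), links connect
elements of consecutive dimensions and encode the boundary relation.  The same
structure represents both geometry complexes (tissue cells, walls, wall edges,
cell corners) and their dual adjacency complexes (cell-centre points, adjacency
links, adjacency triangles, adjacency tetrahedra).

Dualization is purely combinatorial: the graph is flipped over, an n-cell
becoming an (N-n)-cell with all incidence links reversed.  Positions are never
carried across — dual geometry is assigned separately by the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np

__all__ = [
    "IncidenceComplex",
    "DualMap",
    "ValidationReport",
    "dualize",
    "validate_complex",
    "boundary",
    "coboundary",
    "neighbors",
    "cell_boundary_closed",
]


class ComplexError(Exception):
    """Structural error in an incidence complex."""


class UnknownElementError(KeyError):
    """Lookup of an element that is not in the complex."""


@dataclass
class IncidenceComplex:
    """Incidence-graph representation of a cellular complex.

    Attributes
    ----------
    top_dim:
        Top dimension N of the complex (0..3).
    positions:
        Optional map 0-cell id -> 3D point (μm).  Pure-topology complexes
        (e.g. freshly dualized ones) leave it empty.
    properties:
        Map (dimension, name) -> {element id: value}.  Properties of
        different dimensions coexist (e.g. "volume" on 3-cells and "area"
        on 2-cells).
    """

    top_dim: int = 3
    _elements: Dict[int, Set[int]] = field(default_factory=dict)
    _boundary: Dict[Tuple[int, int], Set[int]] = field(default_factory=dict)
    _coboundary: Dict[Tuple[int, int], Set[int]] = field(default_factory=dict)
    positions: Dict[int, np.ndarray] = field(default_factory=dict)
    properties: Dict[Tuple[int, str], Dict] = field(default_factory=dict)
    _next_id: int = 0

    # -- construction ------------------------------------------------------

    def add_element(self, dim: int, element_id: Optional[int] = None,
                    boundary: Iterable[int] = ()) -> int:
        """Add an n-cell with the given (dim-1)-cell boundary ids.

        Ids are opaque integers; if ``element_id`` is None a fresh one is
        allocated.  Boundary elements must already exist.
        """
        if not (0 <= dim <= self.top_dim):
            raise ComplexError(f"dimension {dim} outside 0..{self.top_dim}")
        if element_id is None:
            element_id = self._next_id
        self._next_id = max(self._next_id, element_id + 1)
        self._elements.setdefault(dim, set())
        if element_id in self._elements[dim]:
            raise ComplexError(f"duplicate {dim}-cell id {element_id}")
        bnd = set(boundary)
        if dim == 0 and bnd:
            raise ComplexError("0-cells have no boundary")
        for b in bnd:
            if b not in self._elements.get(dim - 1, set()):
                raise ComplexError(
                    f"boundary element {b} of {dim}-cell {element_id} "
                    f"is not a {dim - 1}-cell of the complex")
        self._elements[dim].add(element_id)
        self._boundary[(dim, element_id)] = bnd
        self._coboundary.setdefault((dim, element_id), set())
        for b in bnd:
            self._coboundary.setdefault((dim - 1, b), set()).add(element_id)
        return element_id

    def remove_element(self, dim: int, element_id: int) -> None:
        """Remove an n-cell; it must have an empty coboundary."""
        self._check(dim, element_id)
        if self._coboundary.get((dim, element_id)):
            raise ComplexError(
                f"{dim}-cell {element_id} still bounds higher cells")
        for b in self._boundary.pop((dim, element_id), set()):
            self._coboundary[(dim - 1, b)].discard(element_id)
        self._coboundary.pop((dim, element_id), None)
        self._elements[dim].discard(element_id)
        for (d, name), mapping in self.properties.items():
            if d == dim:
                mapping.pop(element_id, None)
        if dim == 0:
            self.positions.pop(element_id, None)

    # -- queries -----------------------------------------------------------

    def elements(self, dim: Optional[int] = None):
        """Ids of all elements, or of all n-cells for a given dimension."""
        if dim is not None:
            return frozenset(self._elements.get(dim, set()))
        return frozenset(
            (d, i) for d, ids in self._elements.items() for i in ids)

    def n_elements(self, dim: int) -> int:
        return len(self._elements.get(dim, set()))

    def has_element(self, dim: int, element_id: int) -> bool:
        return element_id in self._elements.get(dim, set())

    def _check(self, dim: int, element_id: int) -> None:
        if not self.has_element(dim, element_id):
            raise UnknownElementError(f"no {dim}-cell with id {element_id}")

    def boundary_of(self, dim: int, element_id: int) -> FrozenSet[int]:
        self._check(dim, element_id)
        return frozenset(self._boundary.get((dim, element_id), set()))

    def coboundary_of(self, dim: int, element_id: int) -> FrozenSet[int]:
        self._check(dim, element_id)
        return frozenset(self._coboundary.get((dim, element_id), set()))

    def vertices_of(self, dim: int, element_id: int) -> FrozenSet[int]:
        """Recursively collect the 0-cells under an element."""
        self._check(dim, element_id)
        frontier = {element_id}
        for d in range(dim, 0, -1):
            frontier = set().union(
                *(self._boundary.get((d, e), set()) for e in frontier))
        return frozenset(frontier)

    def set_property(self, dim: int, name: str, element_id: int, value) -> None:
        self._check(dim, element_id)
        self.properties.setdefault((dim, name), {})[element_id] = value

    def get_property(self, dim: int, name: str) -> Dict:
        return self.properties.get((dim, name), {})

    def copy(self) -> "IncidenceComplex":
        out = IncidenceComplex(top_dim=self.top_dim)
        out._elements = {d: set(s) for d, s in self._elements.items()}
        out._boundary = {k: set(v) for k, v in self._boundary.items()}
        out._coboundary = {k: set(v) for k, v in self._coboundary.items()}
        out.positions = {k: np.array(v) for k, v in self.positions.items()}
        out.properties = {k: dict(v) for k, v in self.properties.items()}
        out._next_id = self._next_id
        return out


@dataclass
class DualMap:
    """Bijection (dim, id) <-> (top_dim - dim, id') between a complex and
    its dual.  With id-reusing dualization the map is identity on ids; it is
    recorded anyway for API stability."""

    top_dim: int
    forward: Dict[Tuple[int, int], Tuple[int, int]]

    def __call__(self, dim: int, element_id: int) -> Tuple[int, int]:
        return self.forward[(dim, element_id)]

    def inverse(self, dim: int, element_id: int) -> Tuple[int, int]:
        return (self.top_dim - dim, element_id)


@dataclass
class ValidationReport:
    """List of violated structural invariants, each naming its element."""

    violations: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when there ARE violations
        return bool(self.violations)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_complex(complex: IncidenceComplex,
                     simplicial: bool = False) -> ValidationReport:
    """Check the cellular-complex axioms on an incidence graph.

    Checks: incidence links connect consecutive dimensions only (structural,
    guaranteed by construction but re-verified), every 1-cell has exactly two
    distinct 0-cells, no dangling n-cells (n >= 1) with empty boundary, and
    boundary closure (every boundary element is in the complex).  With
    ``simplicial=True`` additionally requires every 2-cell to have exactly 3
    bounding 1-cells and every 3-cell exactly 4 bounding 2-cells.
    """
    report = ValidationReport()
    for dim in range(complex.top_dim + 1):
        for eid in complex.elements(dim):
            bnd = complex.boundary_of(dim, eid)
            if dim >= 1 and not bnd:
                report.violations.append(
                    f"dangling {dim}-cell {eid}: empty boundary")
            for b in bnd:
                if not complex.has_element(dim - 1, b):
                    report.violations.append(
                        f"{dim}-cell {eid}: boundary {b} not in complex")
            if dim == 1 and len(bnd) != 2:
                report.violations.append(
                    f"1-cell {eid}: {len(bnd)} incident 0-cells (expected 2)")
            if simplicial:
                if dim == 2 and len(bnd) != 3:
                    report.violations.append(
                        f"2-cell {eid}: {len(bnd)} bounding edges (expected 3)")
                if dim == 3 and len(bnd) != 4:
                    report.violations.append(
                        f"3-cell {eid}: {len(bnd)} bounding faces (expected 4)")
    return report


def dualize(complex: IncidenceComplex,
            top_dim: Optional[int] = None) -> Tuple[IncidenceComplex, DualMap]:
    """Flip the incidence graph over: n-cells become (N-n)-cells.

    All elements and their topological relationships are preserved with the
    dimensions swapped and the incidence links reversed.  The dual carries no
    positions — geometry is assigned by the caller.  Element ids are reused,
    so the returned :class:`DualMap` is identity on ids.
    """
    if top_dim is None:
        top_dim = complex.top_dim
    # graph integrity only: boundary closure and no dangling elements.  The
    # stricter cellular axioms (e.g. every edge has two vertices) need not
    # hold for objects that are themselves duals — an edge dual to a
    # boundary (infinite-interface) triangle legitimately has one vertex —
    # and dualization must remain an involution on them.
    violations = []
    for dim in range(top_dim + 1):
        for eid in complex.elements(dim):
            bnd = complex.boundary_of(dim, eid)
            if dim >= 1 and not bnd:
                violations.append(f"dangling {dim}-cell {eid}")
            for b in bnd:
                if not complex.has_element(dim - 1, b):
                    violations.append(
                        f"{dim}-cell {eid}: missing boundary {b}")
    if violations:
        raise ComplexError("invalid complex: " + "; ".join(violations))
    dual = IncidenceComplex(top_dim=top_dim)
    forward: Dict[Tuple[int, int], Tuple[int, int]] = {}
    # build top-down in the source = bottom-up in the dual, so that boundary
    # (= source coboundary) elements exist when each dual element is added
    for dim in range(top_dim, -1, -1):
        for eid in sorted(complex.elements(dim)):
            dual.add_element(top_dim - dim, element_id=eid,
                            boundary=() if dim == top_dim
                            else complex.coboundary_of(dim, eid))
            forward[(dim, eid)] = (top_dim - dim, eid)
    return dual, DualMap(top_dim=top_dim, forward=forward)


def boundary(complex: IncidenceComplex, dim: int,
             element_id: int) -> FrozenSet[int]:
    """Ids of the (dim-1)-cells bounding an element."""
    return complex.boundary_of(dim, element_id)


def coboundary(complex: IncidenceComplex, dim: int,
               element_id: int) -> FrozenSet[int]:
    """Ids of the (dim+1)-cells the element bounds."""
    return complex.coboundary_of(dim, element_id)


def neighbors(complex: IncidenceComplex, dim: int,
              element_id: int) -> FrozenSet[int]:
    """Same-dimension elements sharing a boundary element (order-free)."""
    complex._check(dim, element_id)
    out: Set[int] = set()
    for b in complex.boundary_of(dim, element_id):
        out |= complex.coboundary_of(dim - 1, b)
    out.discard(element_id)
    return frozenset(out)


def cell_boundary_closed(mesh: IncidenceComplex, cell_id: int) -> bool:
    """True iff the cell's boundary triangles form a closed surface.

    Every edge of the cell's boundary triangles must belong to exactly two of
    that cell's triangles — the watertightness required for voxelization and
    finite-element use.
    """
    mesh._check(3, cell_id)
    tris = mesh.boundary_of(3, cell_id)
    edge_count: Dict[int, int] = {}
    for t in tris:
        for e in mesh.boundary_of(2, t):
            edge_count[e] = edge_count.get(e, 0) + 1
    return bool(edge_count) and all(c == 2 for c in edge_count.values())


# -- simplicial builders ---------------------------------------------------

def simplicial_from_tetrahedra(tetrahedra, positions=None,
                               triangles=()) -> IncidenceComplex:
    """Build a full simplicial 3-complex from label quadruples.

    Vertices reuse the labels as 0-cell ids.  Edges, triangles and tetrahedra
    get sequential ids; the defining label tuple of every simplex is stored
    under the ``"labels"`` property of its dimension.  Extra standalone
    ``triangles`` (label triples not covered by any tetrahedron, e.g. a
    2.5D layer surface) may be supplied.
    """
    tets = sorted({tuple(sorted(t)) for t in tetrahedra})
    extra_tris = sorted({tuple(sorted(t)) for t in triangles})
    C = IncidenceComplex(top_dim=3)
    verts = sorted({v for t in tets for v in t}
                   | {v for t in extra_tris for v in t})
    for v in verts:
        C.add_element(0, element_id=v)
        C.set_property(0, "labels", v, (v,))
        if positions is not None and v in positions:
            C.positions[v] = np.asarray(positions[v], dtype=float)
    C._next_id = max(verts, default=-1) + 1

    from itertools import combinations
    edge_ids: Dict[Tuple[int, int], int] = {}
    tri_ids: Dict[Tuple[int, int, int], int] = {}
    all_tris = sorted({tuple(sorted(p)) for t in tets
                       for p in combinations(t, 3)} | set(extra_tris))
    all_edges = sorted({tuple(sorted(p)) for t in all_tris
                        for p in combinations(t, 2)})
    for e in all_edges:
        eid = C.add_element(1, boundary=e)
        C.set_property(1, "labels", eid, e)
        edge_ids[e] = eid
    for t in all_tris:
        tid = C.add_element(
            2, boundary=[edge_ids[tuple(sorted(p))]
                         for p in combinations(t, 2)])
        C.set_property(2, "labels", tid, t)
        tri_ids[t] = tid
    for q in tets:
        qid = C.add_element(
            3, boundary=[tri_ids[tuple(sorted(p))]
                         for p in combinations(q, 3)])
        C.set_property(3, "labels", qid, q)
    return C


def simplex_labels(C: IncidenceComplex, dim: int):
    """Sorted label tuples of all dim-simplices of a complex built by
    :func:`simplicial_from_tetrahedra` (falls back to vertex traversal)."""
    lab = C.get_property(dim, "labels")
    if len(lab) == C.n_elements(dim):
        return {tuple(sorted(v)) for v in lab.values()}
    return {tuple(sorted(C.vertices_of(dim, e))) for e in C.elements(dim)}
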