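"""Adjacency extraction from 3D segmented (labeled) tissue images.

A segmented image assigns an integer label per voxel, one 26-connected region
per cell, with a designated background label present on the image border (the
tissue never touches the stack boundary).  From this voxel lattice we extract
everything the dual reconstruction needs:

* cell barycenters (centres of mass of the regions, in μm),
* adjacency edges (pairs of labels with 6-connected face contacts) and their
  wall areas,
* adjacency triangles and tetrahedra (label triples/quadruples co-occurring in
  2x2x2 voxel cubes — the 3D generalization of pixel squares containing at
  least three labels),
* the epidermal layering (L1 = background-adjacent, L2 = below L1),
* cell-corner points (mean position of the cubes where 4 cells, or 3 cells
  plus background, meet),
* the binary isosurface of the tissue used as a projection target.

Conventions: arrays are indexed (z, y, x); voxel index (k, j, i) maps to the
world point ((k+0.5)·vz, (j+0.5)·vy, (i+0.5)·vx) in μm (voxel-centre
convention), and all world coordinates follow the same (z, y, x) axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Set, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "SegmentedImage",
    "ImageAdjacencies",
    "cell_barycenters",
    "extract_adjacencies",
    "layer_assignment",
    "cell_corner_points",
    "binary_isosurface",
]

DEFAULT_BACKGROUND = 1


@dataclass
class SegmentedImage:
    """3D integer label lattice with voxel size (μm) and background label."""

    labels: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_label: int = DEFAULT_BACKGROUND

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be 3 positive floats")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs != self.background_label]

    def world_points(self, indices: np.ndarray) -> np.ndarray:
        """Voxel (k,j,i) indices -> world (z,y,x) coordinates in μm."""
        return (np.asarray(indices, dtype=float) + 0.5) * \
            np.asarray(self.voxel_size)

    def validate(self) -> None:
        """Raise if the border carries non-background voxels."""
        lab = self.labels
        border = np.concatenate([
            lab[0].ravel(), lab[-1].ravel(),
            lab[:, 0].ravel(), lab[:, -1].ravel(),
            lab[:, :, 0].ravel(), lab[:, :, -1].ravel()])
        if not np.all(border == self.background_label):
            raise ValueError(
                "tissue touches the image border (background must frame it)")


@dataclass
class ImageAdjacencies:
    """All adjacency information extracted from one segmented image."""

    barycenters: Dict[int, np.ndarray] = field(default_factory=dict)
    edges: Set[FrozenSet[int]] = field(default_factory=set)
    triangles: Set[FrozenSet[int]] = field(default_factory=set)
    tetrahedra: Set[FrozenSet[int]] = field(default_factory=set)
    surface_cells: Set[int] = field(default_factory=set)
    layers: Dict[int, str] = field(default_factory=dict)
    corner_points: Dict[FrozenSet[int], np.ndarray] = field(default_factory=dict)
    wall_areas: Dict[FrozenSet[int], float] = field(default_factory=dict)
    background_label: int = DEFAULT_BACKGROUND

    def cell_edges(self, walls_only: bool = True) -> Set[Tuple[int, int]]:
        """Non-background adjacency pairs as sorted tuples.

        With ``walls_only`` (default) a pair counts as adjacent only if the
        two cells share an actual wall (positive face-contact area); pairs
        present merely through cube co-occurrence (corner contacts) are part
        of ``edges`` for simplex closure but are not cell adjacencies.
        """
        bg = self.background_label
        out = {tuple(sorted(e)) for e in self.edges if bg not in e}
        if walls_only and self.wall_areas:
            out = {e for e in out
                   if self.wall_areas.get(frozenset(e), 0.0) > 0.0}
        return out

    def has_wall(self, a: int, b: int) -> bool:
        return self.wall_areas.get(frozenset((a, b)), 0.0) > 0.0


def cell_barycenters(image: SegmentedImage) -> Dict[int, np.ndarray]:
    """Per-label unweighted mean of voxel-centre world coordinates (μm)."""
    labs = image.cell_labels()
    if labs.size == 0:
        return {}
    coms = ndimage.center_of_mass(
        np.ones_like(image.labels, dtype=np.uint8), image.labels, labs)
    vs = np.asarray(image.voxel_size)
    return {int(l): (np.asarray(c) + 0.5) * vs for l, c in zip(labs, coms)}


def _face_contacts(lab: np.ndarray, axis: int):
    """Pairs of 6-connected face-neighbour labels along one axis, with counts."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    a = lab[tuple(sl_a)].ravel()
    b = lab[tuple(sl_b)].ravel()
    diff = a != b
    a, b = a[diff], b[diff]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    pairs = np.stack([lo, hi], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return uniq, counts


def _cube_label_sets(lab: np.ndarray):
    """Distinct-label multisets of every 2x2x2 voxel cube.

    Returns an (n_cubes, 8) array of the cube corner labels plus the cube
    lower-corner index grid shape, for cubes with >= 3 distinct labels.
    """
    stacks = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                stacks.append(lab[dz:lab.shape[0] - 1 + dz,
                                  dy:lab.shape[1] - 1 + dy,
                                  dx:lab.shape[2] - 1 + dx])
    cubes = np.stack([s.reshape(-1) for s in stacks], axis=1)
    cubes_sorted = np.sort(cubes, axis=1)
    distinct = (np.diff(cubes_sorted, axis=1) != 0).sum(axis=1) + 1
    return cubes_sorted, distinct


def extract_adjacencies(image: SegmentedImage) -> ImageAdjacencies:
    """Extract edges, triangles, tetrahedra, wall areas and layers.

    Edges come from 6-connected face contacts (26-connectivity would create
    spurious point contacts); triples and quadruples from label co-occurrence
    in 2x2x2 cubes.  Cubes containing 5 or more labels contribute all their
    4-subsets as candidate tetrahedra — disambiguation is left to the
    optimization.  Wall areas are face-count areas in μm².
    """
    lab = image.labels
    bg = image.background_label
    adj = ImageAdjacencies(background_label=bg)
    adj.barycenters = cell_barycenters(image)

    vz, vy, vx = image.voxel_size
    face_area = {0: vy * vx, 1: vz * vx, 2: vz * vy}
    wall: Dict[FrozenSet[int], float] = {}
    for axis in range(3):
        uniq, counts = _face_contacts(lab, axis)
        for (lo, hi), c in zip(uniq, counts):
            key = frozenset((int(lo), int(hi)))
            wall[key] = wall.get(key, 0.0) + float(c) * face_area[axis]
    adj.wall_areas = wall
    adj.edges = set(wall.keys())

    cubes_sorted, distinct = _cube_label_sets(lab)
    for want, target in ((3, adj.triangles), (4, adj.tetrahedra)):
        mask = distinct >= want
        if not mask.any():
            continue
        sel = cubes_sorted[mask]
        for row in np.unique(sel, axis=0):
            labs = sorted(set(int(v) for v in row))
            for combo in combinations(labs, want):
                target.add(frozenset(combo))
    # simplex closure: every face of every extracted simplex is extracted
    for quad in adj.tetrahedra:
        for tri in combinations(sorted(quad), 3):
            adj.triangles.add(frozenset(tri))
    for tri in adj.triangles:
        for pair in combinations(sorted(tri), 2):
            adj.edges.add(frozenset(pair))
            adj.wall_areas.setdefault(frozenset(pair), 0.0)

    adj.surface_cells = {next(iter(e - {bg}))
                         for e in adj.edges if bg in e and len(e) == 2}
    adj.layers = layer_assignment(adj)
    adj.corner_points = cell_corner_points(image)
    return adj


def layer_assignment(adj: ImageAdjacencies) -> Dict[int, str]:
    """Classify cells into epidermal L1, subepidermal L2, or deeper.

    L1 cells touch the background; L2 cells touch an L1 cell but not the
    background.  The two layers are disjoint by construction, matching the
    anticlinal separation of the meristem's outer layers.  "Touching" means
    sharing a wall (positive face-contact area); corner-only contacts do not
    make a cell epidermal.
    """
    bg = adj.background_label
    cells = set(adj.barycenters.keys()) or \
        {v for e in adj.edges for v in e if v != bg}

    def touching(a, b):
        if adj.wall_areas:
            return adj.has_wall(a, b)
        return frozenset((a, b)) in adj.edges

    l1 = {c for c in cells if touching(c, bg)}
    if not l1:
        raise ValueError("no cell touches the background; the tissue must be "
                         "framed by background voxels")
    l2 = {c for c in cells - l1 if any(touching(c, n) for n in l1)}
    layers = {}
    for c in sorted(cells):
        layers[c] = "L1" if c in l1 else ("L2" if c in l2 else "deeper")
    return layers


def cell_corner_points(image: SegmentedImage) -> Dict[FrozenSet[int], np.ndarray]:
    """Mean world position of the 2x2x2 cubes where each 4-label set meets.

    Interior corners are quadruples of cell labels; surface corners are
    triples of cells plus the background label.  The point assigned to a
    corner is the mean of the centres of all cubes containing exactly that
    label set (cube centre = lower corner index + 1 voxel).
    """
    lab = image.labels
    cubes_sorted, distinct = _cube_label_sets(lab)
    mask = distinct >= 4
    out: Dict[FrozenSet[int], list] = {}
    if mask.any():
        idx = np.nonzero(mask)[0]
        shape = (lab.shape[0] - 1, lab.shape[1] - 1, lab.shape[2] - 1)
        kji = np.stack(np.unravel_index(idx, shape), axis=1)
        centers = (kji + 1.0) * np.asarray(image.voxel_size)
        sel = cubes_sorted[mask]
        for row, c in zip(sel, centers):
            labs = sorted(set(int(v) for v in row.tolist()))
            # cubes where 5+ labels graze contribute every 4-subset, like
            # the tetrahedron extraction; the optimization picks among them
            for combo in combinations(labs, 4):
                out.setdefault(frozenset(combo), []).append(c)
    return {k: np.mean(v, axis=0) for k, v in out.items()}


def binary_isosurface(image: SegmentedImage):
    """Marching-cubes surface of the foreground mask, in world coordinates.

    Returns ``(vertices, triangles)``; used as a projection target for
    surface mesh vertices.  Raises on an empty foreground.
    """
    mask = (image.labels != image.background_label).astype(np.uint8)
    if not mask.any():
        raise ValueError("empty foreground: no non-background voxels")
    verts, faces, _, _ = measure.marching_cubes(
        mask, level=0.5, spacing=image.voxel_size)
    # marching_cubes positions voxel i at i*spacing; our centres sit at
    # (i+0.5)*spacing
    verts = verts + 0.5 * np.asarray(image.voxel_size)
    return verts, faces
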