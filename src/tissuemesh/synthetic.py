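"""Synthetic segmented tissues with exact ground truth.

Meristematic tissue is well approximated by an (anisotropic) Voronoi
tessellation of the cell centres; the generators here rasterize such
tessellations into labeled images while keeping the *exact* (non-rasterized)
ground truth: the adjacency graph of the generators clipped to the domain,
the analytic corner (Voronoi-vertex) positions, and the layer identity of
every cell.  Two tissues are provided:

* a box-domain Voronoi tissue with a per-axis anisotropy knob — anisotropic
  cells are the regime where the plain Delaunay/Voronoi construction gets
  adjacencies wrong and the adjacency-complex optimization has to fix them;
* a layered dome (hemispherical cap over a base plane) with seeds placed in
  depth bands below the free surface, emulating the L1/L2/inner organisation
  of the shoot apical meristem.

Anisotropy uses an axis-scaled Euclidean metric (diagonal metric): distances
along axis ``i`` are divided by ``anisotropy[i]``, so larger values elongate
cells along that axis.  In the scaled coordinates ``p' = p / a`` the
tessellation is an ordinary Voronoi diagram, which is what makes the exact
ground truth computable (Delaunay candidates + a linear feasibility test for
clipping to the domain).

Labels: background = 1, cells 2..n+1.  All generators are deterministic
under ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import linprog
from scipy.spatial import Delaunay, cKDTree

from .geom import circumsphere_center, DegenerateSimplexError
from .image_adjacency import SegmentedImage

__all__ = [
    "SyntheticTissue",
    "generate_voronoi_tissue",
    "generate_layered_dome",
    "degrade",
]

BACKGROUND = 1


@dataclass
class SyntheticTissue:
    """A rasterized tissue plus its exact generative ground truth."""

    image: SegmentedImage
    seeds: Dict[int, np.ndarray]
    true_adjacency: Set[Tuple[int, int]]
    true_corners: Dict[FrozenSet[int], np.ndarray] = field(default_factory=dict)
    layer_truth: Dict[int, str] = field(default_factory=dict)
    rng_seed: int = 0
    anisotropy: Tuple[float, float, float] = (1.0, 1.0, 1.0)


def _perturbed_grid_seeds(n: int, lo: np.ndarray, hi: np.ndarray,
                          jitter: float, rng: np.random.Generator) -> np.ndarray:
    """n seeds on a jittered grid inside the box [lo, hi] (world μm)."""
    g = int(np.ceil(n ** (1 / 3)))
    extent = hi - lo
    cell = extent / g
    idx = np.stack(np.meshgrid(*[np.arange(g)] * 3, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    chosen = rng.choice(len(idx), size=n, replace=False)
    centers = lo + (idx[chosen] + 0.5) * cell
    offsets = (rng.uniform(-0.5, 0.5, size=(n, 3))) * cell * jitter
    return centers + offsets


def _voronoi_box_adjacency(scaled_seeds: np.ndarray, lo: np.ndarray,
                           hi: np.ndarray) -> Set[Tuple[int, int]]:
    """Exact contacts of a Voronoi diagram clipped to a box.

    Candidate pairs are the Delaunay edges of the (scaled) seeds — clipping a
    Voronoi diagram to a convex box can only remove contacts, never add.  A
    pair is kept iff a point exists in the box that is equidistant from the
    two seeds and no farther from them than from any other seed: a linear
    feasibility problem (bisector equality + dominance half-spaces + box).
    """
    n = len(scaled_seeds)
    if n < 5:  # too few points for a tetrahedrization: test all pairs
        cand = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        tri = Delaunay(scaled_seeds)
        cand = set()
        for simplex in tri.simplices:
            s = sorted(int(v) for v in simplex)
            for i in range(4):
                for j in range(i + 1, 4):
                    cand.add((s[i], s[j]))
    sq = (scaled_seeds ** 2).sum(axis=1)
    out: Set[Tuple[int, int]] = set()
    for (i, j) in sorted(cand):
        a_eq = 2.0 * (scaled_seeds[j] - scaled_seeds[i])[None, :]
        b_eq = [sq[j] - sq[i]]
        others = [k for k in range(n) if k not in (i, j)]
        # d(p, s_i) <= d(p, s_k)  <=>  2(s_k - s_i)·p <= |s_k|² - |s_i|²
        a_ub = 2.0 * (scaled_seeds[others] - scaled_seeds[i])
        b_ub = sq[others] - sq[i]
        res = linprog(c=np.zeros(3), A_ub=a_ub, b_ub=b_ub,
                      A_eq=a_eq, b_eq=b_eq,
                      bounds=list(zip(lo, hi)), method="highs")
        if res.status == 0:
            out.add((i, j))
    return out


def _rasterize_nearest_seed(shape, seeds_scaled: np.ndarray,
                            domain_mask: np.ndarray,
                            inv_anisotropy: np.ndarray,
                            labels_of_seeds: np.ndarray) -> np.ndarray:
    """Assign each in-domain voxel the label of its nearest (scaled) seed."""
    lab = np.full(shape, BACKGROUND, dtype=np.int32)
    kji = np.argwhere(domain_mask)
    pts = (kji + 0.5) * inv_anisotropy
    tree = cKDTree(seeds_scaled)
    _, nearest = tree.query(pts, workers=-1)
    lab[tuple(kji.T)] = labels_of_seeds[nearest]
    return lab


def generate_voronoi_tissue(n_cells: int = 60,
                            resolution: int = 64,
                            anisotropy: Tuple[float, float, float] = (1, 1, 1),
                            jitter: float = 0.5,
                            rng_seed: int = 0,
                            margin: int = 2,
                            voxel_size: Tuple[float, float, float] = (1, 1, 1),
                            ) -> SyntheticTissue:
    """Box-domain anisotropic Voronoi tissue with exact ground truth.

    The tissue fills the image except a ``margin``-voxel background frame.
    Seeds are sampled on a jittered grid (``jitter`` in [0, 1] voxel-cell
    units); each in-domain voxel takes the label of the nearest seed under
    the axis-scaled metric.  Ground truth adjacency and corner points come
    from the exact diagram of the generators, not the rasterization.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if resolution < 32:
        raise ValueError("resolution must be >= 32")
    rng = np.random.default_rng(rng_seed)
    shape = (resolution,) * 3
    a = np.asarray(anisotropy, dtype=float)
    lo = np.full(3, float(margin))
    hi = np.asarray(shape, dtype=float) - margin
    # keep seeds off the frame so every cell has interior volume
    pad = 0.05 * (hi - lo)
    seeds = _perturbed_grid_seeds(n_cells, lo + pad, hi - pad, jitter, rng)
    if len(np.unique(np.floor(seeds).astype(int), axis=0)) < n_cells:
        raise ValueError("resolution too low: two seeds fall in one voxel")
    labels = np.arange(2, n_cells + 2)

    inv_a = 1.0 / a
    seeds_scaled = seeds * inv_a
    dom = np.zeros(shape, dtype=bool)
    dom[margin:resolution - margin,
        margin:resolution - margin,
        margin:resolution - margin] = True
    lab = _rasterize_nearest_seed(shape, seeds_scaled, dom, inv_a, labels)
    image = SegmentedImage(lab, voxel_size=voxel_size,
                           background_label=BACKGROUND)

    adj_idx = _voronoi_box_adjacency(seeds_scaled, lo * inv_a, hi * inv_a)
    true_adjacency = {(int(labels[i]), int(labels[j])) for i, j in adj_idx}

    # analytic corners: circumcentres of scaled-Delaunay tets inside the box
    corners: Dict[FrozenSet[int], np.ndarray] = {}
    slo, shi = lo * inv_a, hi * inv_a
    simplices = Delaunay(seeds_scaled).simplices if n_cells >= 5 else []
    for simplex in simplices:
        try:
            c = circumsphere_center(seeds_scaled[simplex])
        except DegenerateSimplexError:
            continue
        if np.all(c >= slo) and np.all(c <= shi):
            key = frozenset(int(labels[v]) for v in simplex)
            corners[key] = c * a
    # geometric layer truth: cells owning part of the domain boundary are L1
    l1 = _box_surface_cells(seeds_scaled, lo * inv_a, hi * inv_a, labels)
    layer_truth = {}
    neigh = {int(l): set() for l in labels}
    for (u, v) in true_adjacency:
        neigh[u].add(v)
        neigh[v].add(u)
    for l in labels:
        l_ = int(l)
        if l_ in l1:
            layer_truth[l_] = "L1"
        elif neigh[l_] & l1:
            layer_truth[l_] = "L2"
        else:
            layer_truth[l_] = "deeper"
    return SyntheticTissue(
        image=image,
        seeds={int(l): s for l, s in zip(labels, seeds * np.asarray(voxel_size))},
        true_adjacency=true_adjacency,
        true_corners={k: v * np.asarray(voxel_size) for k, v in corners.items()},
        layer_truth=layer_truth,
        rng_seed=rng_seed,
        anisotropy=tuple(a),
    )


def _box_surface_cells(seeds_scaled, lo, hi, labels, samples: int = 48):
    """Cells whose Voronoi region touches a face of the (scaled) box."""
    tree = cKDTree(seeds_scaled)
    out = set()
    lin = [np.linspace(lo[d], hi[d], samples) for d in range(3)]
    for axis in range(3):
        for val in (lo[axis], hi[axis]):
            axes = [d for d in range(3) if d != axis]
            g = np.meshgrid(lin[axes[0]], lin[axes[1]], indexing="ij")
            pts = np.zeros((samples * samples, 3))
            pts[:, axis] = val
            pts[:, axes[0]] = g[0].ravel()
            pts[:, axes[1]] = g[1].ravel()
            _, nearest = tree.query(pts, workers=-1)
            out |= {int(labels[i]) for i in np.unique(nearest)}
    return out


def generate_layered_dome(n_L1: int = 32, n_L2: int = 32, n_inner: int = 8,
                          resolution: int = 64, rng_seed: int = 0,
                          margin: int = 2,
                          voxel_size: Tuple[float, float, float] = (1, 1, 1),
                          ) -> SyntheticTissue:
    """Layered dome tissue emulating the meristem's L1/L2 organisation.

    The domain is a ball (a dome seen from every direction; a planar cut
    would expose the deeper layers to the background at the cut, which is
    exactly the part of a real acquisition the layered reconstruction does
    not use).  The construction is columnar, mirroring the clonal
    organisation of the meristem's outer layers: anchor directions are
    chosen on the sphere by farthest-point sampling (bounded coverage
    radius), and each layer's seed sits on the anchor's inward radius at the
    layer's depth.  For a convex domain with radial columns and sufficient
    anchor coverage, every surface point is closer to an L1 seed than to any
    deeper seed, so the stratification (L1 touches background, L2 touches
    only L1, the bulk sits deeper) is guaranteed and the recorded layer
    truth is exact.  With ``n_L2 < n_L1`` the L2 anchors are a
    farthest-point subsample of the L1 anchors (unshielded columns simply
    carry deeper L1 cells); the defaults use full shielding.
    """
    for name, n in (("n_L1", n_L1), ("n_L2", n_L2), ("n_inner", n_inner)):
        if n < 3:
            raise ValueError(f"{name} must be >= 3")
    if n_L2 > n_L1:
        raise ValueError("n_L2 > n_L1 would leave L2 columns unshielded")
    rng = np.random.default_rng(rng_seed)
    shape = (resolution,) * 3
    res = float(resolution)
    radius = (res - 2 * margin - 2) / 2.0
    center = np.full(3, res / 2.0)

    # layer seed depths below the free surface (fractions of the radius)
    d_l1 = 0.10 * radius
    d_l2 = 0.32 * radius
    d_in = 0.50 * radius
    if (d_l2 - d_l1) < 2.0:
        raise ValueError("shell spacing below voxel size; raise resolution")

    # anchor directions: farthest-point sample of a dense direction cloud
    cloud = rng.normal(size=(4096, 3))
    cloud /= np.linalg.norm(cloud, axis=1, keepdims=True)
    chosen = [0]
    dist = np.arccos(np.clip(cloud @ cloud[0], -1, 1))
    while len(chosen) < n_L1:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.arccos(np.clip(cloud @ cloud[nxt], -1, 1)))
    directions = cloud[chosen]

    def farthest_subset(idx_pool, n):
        chosen = [idx_pool[0]]
        d = np.arccos(np.clip(directions[idx_pool] @ directions[chosen[0]],
                              -1, 1))
        while len(chosen) < n:
            nxt = int(np.argmax(d))
            chosen.append(idx_pool[nxt])
            d = np.minimum(d, np.arccos(np.clip(
                directions[idx_pool] @ directions[idx_pool[nxt]], -1, 1)))
        return sorted(chosen)

    jit = 0.3
    l1_seeds = center + (radius - d_l1) * directions
    l2_idx = farthest_subset(list(range(n_L1)), n_L2)
    l2_seeds = center + (radius - d_l2) * directions[l2_idx]
    in_idx = farthest_subset(list(range(n_L1)), n_inner)
    in_seeds = center + (radius - d_in) * directions[in_idx]
    seeds = np.vstack([l1_seeds, l2_seeds, in_seeds])
    seeds += rng.uniform(-jit, jit, seeds.shape)

    labels = np.arange(2, len(seeds) + 2)
    layer_truth = {}
    for i, l in enumerate(labels):
        layer_truth[int(l)] = ("L1" if i < n_L1 else
                               "L2" if i < n_L1 + n_L2 else "deeper")

    kji = np.indices(shape).reshape(3, -1).T + 0.5
    dom = (np.linalg.norm(kji - center, axis=1) <= radius).reshape(shape)
    lab = _rasterize_nearest_seed(shape, seeds, dom, np.ones(3), labels)
    image = SegmentedImage(lab, voxel_size=voxel_size,
                           background_label=BACKGROUND)

    # ground-truth adjacency: exact Voronoi contacts clipped to the domain's
    # bounding box, then restricted to pairs whose regions actually touch in
    # the rasterization (handles the spherical clip)
    lo = center - radius
    hi = center + radius
    box_adj = _voronoi_box_adjacency(seeds, lo, hi)
    touching = _rasterized_contacts(lab, BACKGROUND)
    true_adjacency = {(int(labels[i]), int(labels[j]))
                      for i, j in box_adj
                      if (int(labels[i]), int(labels[j])) in touching}

    tri = Delaunay(seeds)
    corners: Dict[FrozenSet[int], np.ndarray] = {}
    for simplex in tri.simplices:
        try:
            c = circumsphere_center(seeds[simplex])
        except DegenerateSimplexError:
            continue
        if np.linalg.norm(c - center) <= radius:
            corners[frozenset(int(labels[v]) for v in simplex)] = c.copy()
    vs = np.asarray(voxel_size)
    return SyntheticTissue(
        image=image,
        seeds={int(l): s * vs for l, s in zip(labels, seeds)},
        true_adjacency=true_adjacency,
        true_corners={k: v * vs for k, v in corners.items()},
        layer_truth=layer_truth,
        rng_seed=rng_seed,
    )


def _rasterized_contacts(lab: np.ndarray, bg: int) -> Set[Tuple[int, int]]:
    """6-connected face-contact pairs of a label image (non-background)."""
    out = set()
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = lab[tuple(sl_a)].ravel()
        b = lab[tuple(sl_b)].ravel()
        m = (a != b) & (a != bg) & (b != bg)
        pairs = np.stack([np.minimum(a[m], b[m]), np.maximum(a[m], b[m])],
                         axis=1)
        out |= {(int(u), int(v)) for u, v in np.unique(pairs, axis=0)}
    return out


def degrade(image: SegmentedImage, swap_fraction: float,
            rng_seed: int = 0) -> SegmentedImage:
    """Noise model: reassign boundary voxels to a neighbouring region.

    Emulates segmentation errors along walls.  Swaps that would disconnect
    the donor region (26-connectivity) or touch the background are rejected,
    so the label set is unchanged.
    """
    if not (0 <= swap_fraction < 0.1):
        raise ValueError("swap_fraction must be in [0, 0.1)")
    lab = image.labels.copy()
    bg = image.background_label
    if swap_fraction == 0:
        return SegmentedImage(lab, image.voxel_size, bg)
    rng = np.random.default_rng(rng_seed)
    structure = np.ones((3, 3, 3), dtype=bool)

    # boundary voxels: non-background with a 6-neighbour of another cell label
    boundary = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(lab, shift, axis=axis)
            boundary |= (lab != rolled) & (lab != bg) & (rolled != bg)
    cand = np.argwhere(boundary)
    n_swaps = int(swap_fraction * len(cand))
    order = rng.permutation(len(cand))
    slices = ndimage.find_objects(lab)
    done = 0
    for row in order:
        if done >= n_swaps:
            break
        k, j, i = cand[row]
        donor = int(lab[k, j, i])
        if donor == bg:
            continue
        neigh_labels = []
        for dk, dj, di in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            v = int(lab[k + dk, j + dj, i + di])
            if v not in (donor, bg):
                neigh_labels.append(v)
        if not neigh_labels:
            continue
        new_label = int(rng.choice(sorted(set(neigh_labels))))
        sl = slices[donor - 1]
        region = lab[sl] == donor
        region[k - sl[0].start, j - sl[1].start, i - sl[2].start] = False
        if not region.any():
            continue
        _, n_comp = ndimage.label(region, structure=structure)
        if n_comp != 1:
            continue
        lab[k, j, i] = new_label
        done += 1
    return SegmentedImage(lab, image.voxel_size, bg)
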