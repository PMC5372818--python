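"""Adjacency-complex optimization and dual reconstruction."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial import Voronoi, cKDTree

from tissuemesh import draco
from tissuemesh.complex_core import (simplex_labels, validate_complex,
                                     cell_boundary_closed)
from tissuemesh.geom import DegenerateSimplexError
from tissuemesh.image_adjacency import ImageAdjacencies


def edges_of(C):
    return {tuple(sorted(e)) for e in simplex_labels(C, 1)}


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 1.0


class TestDelaunay:
    def test_four_points_one_tetrahedron(self):
        b = {2: [0, 0, 0], 3: [1, 0, 0], 4: [0, 1, 0], 5: [0, 0, 1]}
        C = draco.delaunay_adjacency(b)
        assert C.n_elements(3) == 1
        assert simplex_labels(C, 3) == {(2, 3, 4, 5)}

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            draco.delaunay_adjacency({2: [0, 0, 0], 3: [1, 0, 0]})

    def test_coplanar_points_raise(self):
        b = {i: [i * 1.0, i * 2.0, 0.0] for i in range(2, 8)}
        with pytest.raises(ValueError):
            draco.delaunay_adjacency(b)

    def test_centroid_of_regular_tetrahedron_gives_four_tets(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        b = {i + 2: pts[i] for i in range(4)}
        b[6] = pts.mean(axis=0)
        C = draco.delaunay_adjacency(b)
        assert C.n_elements(3) == 4

    def test_empty_circumsphere_property(self, voronoi_adj):
        # brute-force oracle: no barycenter strictly inside any
        # circumsphere of a Delaunay tetrahedron
        C = draco.delaunay_adjacency(voronoi_adj.barycenters)
        pts = voronoi_adj.barycenters
        for tet in simplex_labels(C, 3):
            c = draco.circumsphere_center(
                np.asarray([pts[v] for v in tet]))
            r = np.linalg.norm(pts[tet[0]] - c)
            for label, p in pts.items():
                if label in tet:
                    continue
                assert np.linalg.norm(p - c) >= r * (1 - 1e-9)


class TestCircumsphere:
    def test_regular_tetrahedron_centre_is_centroid(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        assert np.allclose(draco.circumsphere_center(pts), [0, 0, 0])

    def test_unit_corner_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                       dtype=float)
        assert np.allclose(draco.circumsphere_center(pts), [0.5, 0.5, 0.5])

    def test_flat_tetrahedron_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                       dtype=float)
        with pytest.raises(DegenerateSimplexError):
            draco.circumsphere_center(pts)


class TestConstrainIntoTetrahedron:
    TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)

    def test_centroid_unchanged(self):
        c = self.TET.mean(axis=0)
        assert np.allclose(draco.constrain_into_tetrahedron(c, self.TET), c)

    def test_margin_zero_point_on_face_unchanged(self):
        p = np.array([0.3, 0.3, 0.0])
        out = draco.constrain_into_tetrahedron(p, self.TET, margin=0.0)
        assert np.allclose(out, p)

    def test_outside_point_matches_sampling_oracle(self):
        rng = np.random.default_rng(1)
        margin = 0.05
        shrunk = (1 - 4 * margin) * self.TET + \
            4 * margin * self.TET.mean(axis=0)
        # dense barycentric sample of the shrunk tetrahedron
        lam = rng.dirichlet(np.ones(4), size=20000)
        samples = lam @ shrunk
        for p in ([2.0, 2.0, 2.0], [-1.0, 0.2, 0.2], [0.4, 0.4, 0.9]):
            out = draco.constrain_into_tetrahedron(
                np.asarray(p), self.TET, margin=margin)
            d_out = np.linalg.norm(out - p)
            d_best = np.min(np.linalg.norm(samples - p, axis=1))
            assert d_out <= d_best + 1e-2


class TestCleanExterior:
    def test_fixed_point_without_violations(self):
        b = {2: [0, 0, 0], 3: [1, 0, 0], 4: [0, 1, 0], 5: [0, 0, 1],
             6: [1, 1, 1]}
        adj = ImageAdjacencies(
            barycenters={k: np.asarray(v, float) for k, v in b.items()},
            wall_areas={frozenset(p): 1.0
                        for p in combinations(b, 2)})
        adj.edges = set(adj.wall_areas)
        C = draco.delaunay_adjacency(b)
        out = draco.clean_exterior(C, adj)
        assert simplex_labels(out, 3) == simplex_labels(C, 3)

    def test_single_stretched_tet_removed_entirely(self):
        b = {2: [0, 0, 0], 3: [1, 0, 0], 4: [0, 1, 0], 5: [0, 0, 30]}
        adj = ImageAdjacencies(
            barycenters={k: np.asarray(v, float) for k, v in b.items()},
            wall_areas={frozenset(p): 1.0 for p in combinations(b, 2)})
        adj.edges = set(adj.wall_areas)
        C = draco.delaunay_adjacency(b)
        with pytest.raises(ValueError):
            draco.clean_exterior(C, adj, max_edge_factor=1.5)

    def test_removes_hull_tents_on_fixture(self, voronoi_tissue, voronoi_adj,
                                           cleaned_complex):
        raw = draco.delaunay_adjacency(voronoi_adj.barycenters)
        truth = voronoi_tissue.true_adjacency
        assert jaccard(edges_of(cleaned_complex), truth) >= \
            jaccard(edges_of(raw), truth)
        assert validate_complex(cleaned_complex, simplicial=True).ok


class TestAdjacencyEnergy:
    def test_zero_weights_zero_total(self, cleaned_complex, voronoi_adj):
        e = draco.adjacency_energy(cleaned_complex, voronoi_adj,
                                   draco.EnergyWeights(0, 0, 0))
        assert e.total == 0.0

    def test_matching_edges_zero_image_term(self):
        b = {2: [0, 0, 0], 3: [1, 0, 0], 4: [0, 1, 0], 5: [0, 0, 1]}
        adj = ImageAdjacencies(
            barycenters={k: np.asarray(v, float) for k, v in b.items()},
            wall_areas={frozenset(p): 1.0 for p in combinations(b, 2)},
            surface_cells=set(b))
        adj.edges = set(adj.wall_areas)
        C = draco.delaunay_adjacency(b)
        e = draco.adjacency_energy(C, adj)
        assert e.e_image == 0.0

    def test_equilateral_tetrahedron_zero_regularity(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        b = {i + 2: pts[i] for i in range(4)}
        adj = ImageAdjacencies(
            barycenters={k: np.asarray(v, float) for k, v in b.items()},
            wall_areas={frozenset(p): 1.0 for p in combinations(b, 2)},
            surface_cells=set(b))
        adj.edges = set(adj.wall_areas)
        C = draco.delaunay_adjacency(b)
        assert draco.adjacency_energy(C, adj).e_regularity == \
            pytest.approx(0.0, abs=1e-9)

    def test_total_is_weighted_sum(self, cleaned_complex, voronoi_adj):
        w = draco.EnergyWeights(1.0, 0.2, 0.3)
        e = draco.adjacency_energy(cleaned_complex, voronoi_adj, w)
        assert e.total == pytest.approx(
            w.w_image * e.e_image + w.w_prior * e.e_prior
            + w.w_regularity * e.e_regularity)


@pytest.fixture(scope="module")
def optimized(cleaned_complex, voronoi_adj):
    sched = draco.AnnealingSchedule(cycles=2, rng_seed=3)
    return draco.optimize_adjacency(cleaned_complex, voronoi_adj,
                                    schedule=sched)


class TestOptimizeAdjacency:
    def test_energy_never_increases_overall(self, optimized, cleaned_complex,
                                            voronoi_adj):
        before = draco.adjacency_energy(cleaned_complex, voronoi_adj).total
        after = draco.adjacency_energy(optimized, voronoi_adj).total
        assert after <= before + 1e-12

    def test_valid_simplicial_complex(self, optimized):
        assert validate_complex(optimized, simplicial=True).ok

    def test_triangles_shared_by_at_most_two_tets(self, optimized):
        for t in optimized.elements(2):
            assert len(optimized.coboundary_of(2, t)) <= 2

    def test_recovers_adjacency_better_than_delaunay(
            self, optimized, voronoi_tissue, voronoi_adj):
        raw = draco.delaunay_adjacency(voronoi_adj.barycenters)
        truth = voronoi_tissue.true_adjacency
        assert jaccard(edges_of(optimized), truth) > \
            jaccard(edges_of(raw), truth)

    def test_deterministic_under_seed(self, cleaned_complex, voronoi_adj):
        sched = draco.AnnealingSchedule(cycles=1, rng_seed=8)
        a = draco.optimize_adjacency(cleaned_complex, voronoi_adj,
                                     schedule=sched)
        b = draco.optimize_adjacency(cleaned_complex, voronoi_adj,
                                     schedule=sched)
        assert simplex_labels(a, 3) == simplex_labels(b, 3)

    def test_energy_log_zero_temperature_monotone(self, optimized):
        zero = [e for _, _, t, e in optimized.energy_log if t == 0.0]
        assert zero == sorted(zero, reverse=True)


class TestDualGeometry:
    def test_pristine_delaunay_matches_voronoi(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 10, size=(20, 3))
        C = draco.delaunay_adjacency({i + 2: pts[i] for i in range(20)})
        D = draco.dual_geometry(C, None)
        vor = Voronoi(pts)
        tree = cKDTree(vor.vertices)
        kind = D.get_property(0, "kind")
        for vid in D.elements(0):
            if kind[vid] != "corner":
                continue
            d, _ = tree.query(D.positions[vid])
            assert d <= 1e-9 * (1 + np.linalg.norm(D.positions[vid]))

    def test_single_tetrahedron_dual_structure(self):
        b = {2: [0, 0, 0], 3: [1, 0, 0], 4: [0, 1, 0], 5: [0, 0, 1]}
        C = draco.delaunay_adjacency(b)
        D = draco.dual_geometry(C, None)
        # one interior vertex, four boundary-capped cells, all watertight
        kinds = list(D.get_property(0, "kind").values())
        assert kinds.count("corner") == 1
        assert D.n_elements(3) == 4
        for cid in D.elements(3):
            assert cell_boundary_closed(D, cid)

    def test_fixture_interior_junctions_have_four_cells(self, dome_dual):
        cells = dome_dual.get_property(0, "cells")
        kind = dome_dual.get_property(0, "kind")
        for vid in dome_dual.elements(0):
            if kind[vid] == "corner":
                assert len(cells[vid]) == 4

    def test_fixture_cells_watertight(self, dome_dual):
        for cid in dome_dual.elements(3):
            assert cell_boundary_closed(dome_dual, cid)

    def test_valid_complex(self, dome_dual):
        assert validate_complex(dome_dual).ok


def _toy_layer_adjacency():
    """Five cells: an L1 triangle over two stacked L2-ish cells, giving two
    equal-weight candidate tetrahedra that geometrically intersect."""
    pos = {2: np.array([0.0, 0.0, 0.0]), 3: np.array([0.0, 4.0, 0.0]),
           4: np.array([0.0, 2.0, 3.0]),
           5: np.array([2.0, 2.0, 1.0]), 6: np.array([2.5, 2.0, 1.0])}
    adj = ImageAdjacencies(barycenters=pos)
    walls = {}
    for pair in combinations(sorted(pos), 2):
        walls[frozenset(pair)] = 10.0
    # equalize: weight of (2,3,4,5) and (2,3,4,6) must tie -> give the pairs
    # with 5 and 6 areas proportional to their distances
    for c in (5, 6):
        for o in (2, 3, 4):
            d = np.linalg.norm(pos[c] - pos[o])
            walls[frozenset((o, c))] = d
    for a, b in (((2, 3)), ((2, 4)), ((3, 4))):
        walls[frozenset((a, b))] = np.linalg.norm(pos[a] - pos[b])
    walls[frozenset((5, 6))] = np.linalg.norm(pos[5] - pos[6])
    adj.wall_areas = walls
    adj.edges = set(walls)
    adj.tetrahedra = {frozenset((2, 3, 4, 5)), frozenset((2, 3, 4, 6))}
    adj.triangles = {frozenset(t) for q in adj.tetrahedra
                     for t in combinations(sorted(q), 3)}
    adj.layers = {2: "L1", 3: "L1", 4: "L1", 5: "L2", 6: "L2"}
    adj.surface_cells = {2, 3, 4}
    return adj


class TestLayerReconstruction:
    def test_weight_zero_when_wall_missing(self):
        adj = _toy_layer_adjacency()
        adj.wall_areas[frozenset((2, 5))] = 0.0
        assert draco.layer_tetra_weight((2, 3, 4, 5), adj) == 0.0

    def test_weight_invariant_to_label_order(self):
        adj = _toy_layer_adjacency()
        w1 = draco.layer_tetra_weight((2, 3, 4, 5), adj)
        w2 = draco.layer_tetra_weight((5, 4, 3, 2), adj)
        assert w1 == pytest.approx(w2)

    def test_bigger_wall_shorter_distance_wins(self):
        adj = _toy_layer_adjacency()
        for o in (2, 3, 4):
            adj.wall_areas[frozenset((o, 5))] *= 3.0
        assert draco.layer_tetra_weight((2, 3, 4, 5), adj) > \
            draco.layer_tetra_weight((2, 3, 4, 6), adj)

    def test_intersecting_tie_broken_lexicographically(self):
        adj = _toy_layer_adjacency()
        w1 = draco.layer_tetra_weight((2, 3, 4, 5), adj)
        w2 = draco.layer_tetra_weight((2, 3, 4, 6), adj)
        assert w1 == pytest.approx(w2)
        C = draco.aggregate_layer_complex(adj, mode="L1L2")
        tets = simplex_labels(C, 3)
        assert tets == {(2, 3, 4, 5)}

    def test_dome_l1l2_covers_both_layers(self, dome_tissue, dome_adj):
        C = draco.aggregate_layer_complex(dome_adj, mode="L1L2")
        verts = {v for t in simplex_labels(C, 3) for v in t}
        wanted = {c for c, l in dome_tissue.layer_truth.items()
                  if l in ("L1", "L2")}
        assert len(verts & wanted) >= 0.9 * len(wanted)

    def test_l1_surface_is_triangle_complex(self, dome_adj):
        C = draco.aggregate_layer_complex(dome_adj, mode="L1")
        assert C.n_elements(3) == 0
        assert C.n_elements(2) > 0
        # manifold surface: every edge in at most two triangles
        for e in C.elements(1):
            assert len(C.coboundary_of(1, e)) <= 2

    def test_no_candidates_raises(self):
        adj = ImageAdjacencies(barycenters={2: np.zeros(3)})
        adj.layers = {2: "L1"}
        with pytest.raises(ValueError):
            draco.aggregate_layer_complex(adj, mode="L1L2")
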