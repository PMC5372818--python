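"""End-to-end reconstruction: segmented image -> optimized tissue mesh.

Chains the stages with a single configuration and a single seed:
adjacency extraction, Delaunay initialization, exterior cleaning, annealed
adjacency optimization (or layered aggregation), dual geometry, star
triangulation, optional refinement/projection/pinning, mesh optimization,
and the ten-estimator quality report.  Identical config + seed + input give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import draco, image_adjacency, quality, stem
from .complex_core import IncidenceComplex, validate_complex
from .config import PipelineConfig
from .image_adjacency import ImageAdjacencies, SegmentedImage
from .stem import TissueMesh

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    adjacencies: ImageAdjacencies
    adjacency_complex: IncidenceComplex
    dual_complex: IncidenceComplex
    mesh: TissueMesh
    report: quality.QualityReport
    report_before_stem: Optional[quality.QualityReport] = None
    energy_logs: Dict[str, List] = field(default_factory=dict)


def run_pipeline(image: SegmentedImage, config: PipelineConfig = None,
                 compare_before_stem: bool = False) -> PipelineResult:
    cfg = config or PipelineConfig()
    image.validate()
    logger.info("pipeline: %d cells, voxel size %s um, seed %d",
                len(image.cell_labels()), image.voxel_size, cfg.rng_seed)

    adj = image_adjacency.extract_adjacencies(image)
    iso = image_adjacency.binary_isosurface(image)
    energy_logs: Dict[str, List] = {}

    if cfg.layers:
        T = draco.aggregate_layer_complex(adj, mode=cfg.layers)
    else:
        T = draco.delaunay_adjacency(adj.barycenters)
        T = draco.clean_exterior(
            T, adj, max_edge_factor=cfg.max_edge_factor,
            sliver_min_dihedral_deg=cfg.sliver_min_dihedral_deg,
            sliver_radius_edge=cfg.sliver_radius_edge, image=image)
        weights = draco.EnergyWeights(cfg.draco_w_image, cfg.draco_w_prior,
                                      cfg.draco_w_regularity)
        schedule = draco.AnnealingSchedule(
            t_start=cfg.draco_t_start, t_end=cfg.draco_t_end,
            cycles=cfg.draco_cycles, cooling_factor=cfg.draco_cooling,
            rng_seed=cfg.rng_seed)
        T = draco.optimize_adjacency(T, adj, weights, schedule,
                                     neighbor_target=cfg.neighbor_target)
        energy_logs["draco"] = T.energy_log
        for cycle, sweep, t, e in T.energy_log:
            logger.info("draco cycle %d sweep %d T=%.4g E=%.6g",
                        cycle, sweep, t, e)
    rep = validate_complex(T, simplicial=cfg.layers != "L1")
    if rep:
        raise RuntimeError("invalid adjacency complex: "
                           + "; ".join(rep.violations))

    if cfg.layers == "L1":
        D = _dual_surface(T)
    else:
        D = draco.dual_geometry(T, adj, isosurface=iso,
                                margin=cfg.constrain_margin)
    mesh = stem.star_triangulate(D)
    if cfg.split_rounds:
        mesh = stem.split_refine(mesh, cfg.split_rounds)
    if cfg.remesh_target:
        mesh = stem.isotropic_remesh(mesh, cfg.remesh_target)
    if cfg.project_surface:
        mesh = stem.project_surface_vertices(mesh, iso)
    if cfg.pin_corners:
        mesh = stem.pin_cell_corners(mesh, adj.corner_points,
                                     background_label=image.background_label)

    report_before = None
    if cfg.layers is None:
        if compare_before_stem:
            report_before = quality.quality_report(
                mesh, image, adj, d0=cfg.d0,
                angle_ref=cfg.angle_reference_deg,
                complexity_ref=cfg.complexity_reference)
        if cfg.run_stem:
            w = stem.StemWeights(
                w_image=cfg.stem_w_image, w_prior=cfg.stem_w_prior,
                w_regularity=cfg.stem_w_regularity,
                shift_radius=cfg.shift_radius,
                schedule=draco.AnnealingSchedule(
                    t_start=cfg.stem_t_start, t_end=cfg.stem_t_end,
                    cycles=cfg.stem_cycles, cooling_factor=cfg.stem_cooling,
                    rng_seed=(cfg.rng_seed + 1) % (2 ** 31)))
            mesh = stem.optimize_mesh(mesh, image, w, isosurface=iso)
            energy_logs["stem"] = mesh.energy_log
            for cycle, sweep, t, e in mesh.energy_log:
                logger.info("stem cycle %d sweep %d T=%.4g E=%.6g",
                            cycle, sweep, t, e)
        report = quality.quality_report(
            mesh, image, adj, d0=cfg.d0, angle_ref=cfg.angle_reference_deg,
            complexity_ref=cfg.complexity_reference)
    else:
        # layered meshes are open shells; the watertight-cell estimators do
        # not apply, report intrinsic terms only
        report = quality.QualityReport()
        report.scores.update(quality.intrinsic_scores(mesh))
        report.scores.pop("_raw", None)
        report.counts = {"cells": int(len(mesh.cell_labels())),
                         "vertices": mesh.n_vertices(),
                         "triangles": mesh.n_triangles()}
    return PipelineResult(adjacencies=adj, adjacency_complex=T,
                          dual_complex=D, mesh=mesh, report=report,
                          report_before_stem=report_before,
                          energy_logs=energy_logs)


def _dual_surface(T: IncidenceComplex) -> IncidenceComplex:
    """2.5D dual of an L1 triangle complex: one polygonal face per cell.

    Each adjacency triangle becomes a vertex at its circumcircle centre
    (clamped into the triangle); each L1 cell becomes the polygon of its
    triangles' dual vertices, closed through midpoints of its boundary
    adjacency edges.
    """
    from collections import defaultdict
    from itertools import combinations

    import numpy as np

    from .draco import EXTERIOR, barycentric_coordinates_tri
    from .geom import (DegenerateSimplexError, circumcircle_center,
                       closest_point_on_triangle)
    from .complex_core import simplex_labels

    tris = sorted(simplex_labels(T, 2))
    if not tris:
        raise ValueError("empty layer complex")
    pts = dict(T.positions)
    edge_owners = defaultdict(list)
    for t in tris:
        for pair in combinations(t, 2):
            edge_owners[pair].append(t)
    tri_center = {}
    for t in tris:
        p = np.asarray([pts[v] for v in t])
        try:
            c = circumcircle_center(p)
        except DegenerateSimplexError:
            c = p.mean(axis=0)
        lam = barycentric_coordinates_tri(c, p)
        if np.any(lam < 0):
            c = closest_point_on_triangle(c, p)
        tri_center[t] = c

    D = IncidenceComplex(top_dim=3)
    vid_of_tri = {}
    for t in tris:
        vid = D.add_element(0)
        D.positions[vid] = tri_center[t]
        D.set_property(0, "cells", vid, frozenset(t))
        D.set_property(0, "is_surface", vid, True)
        vid_of_tri[t] = vid
    vid_of_bedge = {}
    for pair, owners in sorted(edge_owners.items()):
        if len(owners) == 1:
            vid = D.add_element(0)
            D.positions[vid] = 0.5 * (np.asarray(pts[pair[0]])
                                      + np.asarray(pts[pair[1]]))
            D.set_property(0, "cells", vid, frozenset(pair) | {EXTERIOR})
            D.set_property(0, "is_surface", vid, True)
            vid_of_bedge[pair] = vid

    eid_of_edge = {}
    for pair, owners in sorted(edge_owners.items()):
        if len(owners) == 2:
            eid = D.add_element(1, boundary=[vid_of_tri[owners[0]],
                                            vid_of_tri[owners[1]]])
        else:
            eid = D.add_element(1, boundary=[vid_of_tri[owners[0]],
                                            vid_of_bedge[pair]])
        eid_of_edge[pair] = eid

    cells = sorted({v for t in tris for v in t})
    for cell in cells:
        # the polygon of a cell: dual edges of the adjacency edges at the
        # cell; open chains (boundary cells) are closed via rim segments
        my_edges = [pair for pair in edge_owners if cell in pair]
        eids = [eid_of_edge[p] for p in my_edges]
        rim = sorted(p for p in my_edges if len(edge_owners[p]) == 1)
        if len(rim) == 2:
            eids.append(D.add_element(1, boundary=[vid_of_bedge[rim[0]],
                                                   vid_of_bedge[rim[1]]]))
        incident = defaultdict(int)
        for eid in eids:
            for vid in D.boundary_of(1, eid):
                incident[vid] += 1
        if any(c != 2 for c in incident.values()):
            logger.warning("L1 dual: cell %d polygon is not closed; skipped",
                           cell)
            continue
        fid = D.add_element(2, boundary=eids)
        D.set_property(2, "interface", fid, (EXTERIOR, cell))
        cid = D.add_element(3, boundary=[fid])
        D.set_property(3, "label", cid, cell)
    return D
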