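# Methods

## The model

A plant tissue at cell resolution is treated as a cellular complex: cells
are convex-ish polyhedra (3-cells) meeting pairwise along polygonal walls
(2-cells), walls meeting along junction lines (1-cells), and junction lines
meeting at corners (0-cells) where — generically — exactly four cells meet
(three plus the outside on the free surface). Its combinatorial dual is a
simplicial complex of adjacencies: one vertex per cell at its barycenter,
one edge per shared wall, one triangle per junction line, one tetrahedron
per corner. The two objects carry the same topological information, and the
incidence-graph data structure (`complex_core`) represents both; dualization
is literally flipping the graph over. An adjacency edge that belongs to
only one adjacency triangle is dual to an infinite (exterior) interface;
geometrically those are clipped to the tissue surface.

The reconstruction problem is therefore: find the adjacency simplicial
complex that best matches a segmented image, and dualize it. The Delaunay
tetrahedrization of the barycenters is the natural initial guess (its dual
is the Voronoi diagram, a fair first model of meristematic tissue), but
anisotropic cell shapes make some Delaunay edges wrong, so the complex is
optimized.

## Adjacency extraction (`image_adjacency`)

From a labeled lattice (one 26-connected region per cell, background frame
at the border; voxel (k,j,i) centre at ((k+0.5)vz, (j+0.5)vy, (i+0.5)vx)
μm) we extract: barycenters (unweighted voxel-centre means); adjacency
edges from 6-connected face contacts with wall areas = face count × face
area (26-connectivity would create spurious point contacts; the staircase
overestimation of wall area is reported uncorrected); triangles and
tetrahedra from label co-occurrence in 2×2×2 cubes, cubes with ≥5 labels
contributing all 4-subsets (ambiguity is resolved later by the energy, not
at extraction); corner points as the mean centre of the cubes where a
4-label set co-occurs (again with ≥5-label cubes contributing their
4-subsets, mirroring the tetrahedron rule); layers (L1 = wall contact with
background, L2 = wall contact with L1 but not background — corner-only
contacts never make a cell epidermal); and the marching-cubes isosurface of
the foreground mask used as a projection target.

## Adjacency optimization (`draco`)

Cleaning: boundary tetrahedra are iteratively removed when they cross the
tissue surface (a vertex pair without an image wall whose barycenter
segment passes through background), contain an edge longer than 3× the
initial median edge, or are slivers (minimal dihedral angle < 5° or
radius/shortest-edge > 4).

Energy: `E = w_image·E_image + w_prior·E_prior + w_reg·E_reg` with defaults
(1.0, 0.1, 0.1). `E_image` = |edges(T) Δ walls(S)| / |walls(S)|. `E_prior` =
mean over interior (non-epidermal) cells of ((degree − 13.2)/13.2)²; 13.2
is an empirical mean neighbour count for interior meristem cells, and
surface cells are excluded because the background truncates their
neighbourhoods. `E_reg` = mean over tetrahedra of (longest/shortest edge −
1). The exact published formulations of the three terms are not available
to us, so these are this package's committed definitions of the three
stated intents; each is swappable.

Moves: 2–3 bistellar flips (two tetrahedra sharing a triangle become three
around a new edge) and edge removals that re-tetrahedrize the link ring of
an interior edge by a fan (ring size 3 is the 3–2 flip; rings up to ~6 are
handled, larger ones are practically absent at these sizes). A move is
admissible only if no triangle ends up in more than two tetrahedra, no cell
loses its last tetrahedron, and the re-tetrahedrized cavity fills exactly
the volume it vacates (this single check rejects overlapping or gapped
configurations). Proposals preferentially target disagreements with the
image: with probability 0.4 an edge-removal on an edge without image
support, 0.3 a flip creating a missing wall edge, otherwise a uniform
move. Acceptance is Metropolis over 3 geometric cooling cycles
(t: 1 → 0.01, ×0.95 per sweep, one proposal per tetrahedron per sweep),
followed by a greedy zero-temperature quench started from the best state
encountered — so the final energy never exceeds the initial one, and the
energy trace at zero temperature is non-increasing by construction. All
randomness comes from one seeded generator.

Dual geometry: each tetrahedron becomes a corner at its circumsphere
centre. The centre is projected back into its (5%-shrunk) tetrahedron
*only* when the local empty-circumsphere test against the flip-neighbours'
apexes fails: for a true Delaunay complex no tetrahedron fails it, so the
dual is exactly the Voronoi diagram (this is also how the package verifies
itself against an independent computational-geometry construction); where
optimization has broken the Delaunay property, the projection prevents the
face intersections it would otherwise cause. Boundary triangles spawn
surface corners at their circumcircle centres projected onto the
isosurface; faces dual to adjacency edges are closed through the surface,
and each surface cell receives exterior cap faces, so every cell of the
dual is watertight by construction, including around non-manifold boundary
fans (face cycles are decomposed per connected component).

Layered reconstruction: candidate tetrahedra are the image-extracted ones
with layer composition 3+1, 1+3 or 2+2 over L1/L2; weight = Σ over vertex
pairs of wall area / barycenter distance, zero if any pair shares no wall.
Greedy best-first aggregation from the highest weight, accepting a
neighbour only if it creates no non-manifold face and no geometric
intersection in the barycentric embedding; ties break lexicographically on
the label tuple. The L1-only mode aggregates triangles the same way and
dualizes to a 2.5D polygonal mesh.

## Mesh enhancement (`stem`)

The dual is star-triangulated (each k-edge interface fans into k triangles
from its boundary-vertex mean). Optional pre-processing, in this fixed
order: 1-to-4 split refinement (midpoints shared across all triangles of an
edge, so total area is conserved exactly and watertightness is preserved);
constrained isotropic remeshing (split > 4/3·target, collapse < 4/5·target
with the full link condition, valence-improving flips, tangential
smoothing — junction lines, corners and interface boundaries are never
collapsed or moved across); projection of surface vertices onto the
isosurface; and pinning of junction vertices to the image corner with the
same incident label set (nearest wins on conflicts; unmatched junctions —
ambiguous configurations the optimization resolved without direct image
support — stay free and are logged).

Energy, same three-term form: image attachment = mean over non-pinned
vertices of squared distance to the nearest wall point compatible with the
vertex's incident interfaces (averaged over them); shape prior = mean over
interfaces of the mean squared distance to the interface's best-fit plane
(flat polygonal walls); regularization = mean triangle eccentricity
(1 − Σ sin(angles)/(3 sin 60°)) plus mean squared (valence − 6) over
interface-interior vertices. The two squared-distance terms are divided by
the voxel diagonal² so the default weights (1.0, 0.5, 0.5) act on
dimensionless, comparable scales.

Moves: vertex shifts inside a sphere of radius half the median edge
(shrinking ×0.9 per cycle; surface vertices re-projected after each shift;
half the proposals walk directly toward the compatible wall points, which
is what makes the descent converge at these problem sizes) and edge flips
strictly interior to a single interface — never across interfaces, so the
dual adjacency is preserved exactly (asserted). Every move is additionally
bounded by a per-cell volume budget: incremental signed-volume tracking
rejects any move that would take a cell beyond ±10% of its input volume.
The temperature scale (1e-4 → 5e-6, ×0.7 per sweep, 2 cycles) matches the
~1e-4 magnitude of single-move energy deltas (the energy is a mean over
thousands of elements); an adaptive zero-temperature quench (up to 12
sweeps, stopping at stagnation) finishes from the best state.

## Quality estimation (`quality`)

Ten scores in [0, 1], 1 ideal, mean reported as average quality:
convexity (cell volume / convex-hull volume); epidermis junction angle
(wedge angles of the three cells around each surface junction, measured in
the junction's fitted tangent plane and rescaled to close at 360°, scored
as 1 − mean|wedge − 120°|/30°); cliques (fraction of junctions with at most
4 cells, 3 on the surface); image accuracy (mean per-cell Jaccard between
segmented regions and the voxelized mesh — parity ray casting along +x with
an ε tie perturbation, verified against a winding-number oracle); corner
distance (reciprocal of mean matched-corner distance against d₀ = √3·0.25
μm, the voxel diagonal at a typical resolution; reported missing, not zero,
when no corner matches); adjacency Jaccard; area deviation (1 − std/(√2 ·
mean area)); eccentricity (mean normalized by 0.5); valence
(1 − mean|valence − 6|/6 over interface-interior vertices, where vertices
on interface boundaries, junction lines and corners are excluded); and
complexity (min(1, 152/triangle incidences per cell); 152 corresponds to a
good triangulation of the space-filling truncated octahedron). Sub-1e-12
relative deviations snap to zero so analytically ideal constructions score
exactly 1. Per-cell Jaccard includes all voxels of each cell, including
background-adjacent ones.

Property computation: per-cell signed volume by the divergence theorem over
an outward orientation derived on demand (orientation is not stored);
per-interface summed triangle area; surface curvature per vertex (Gaussian
by angle deficit over barycentric one-third areas, mean by the cotangent
Laplacian, principal directions from a local quadric fit of the one-ring).

## Synthetic tissues (`synthetic`)

The box generator rasterizes an axis-scaled (diagonal-metric) Voronoi
tessellation of jittered-grid seeds; anisotropy along one axis is exactly
the regime where Delaunay adjacencies break and the optimization has
something to fix. Ground truth is exact, not rasterized: a pair of cells is
truly adjacent iff a point in the domain is power-equidistant and
undominated — a linear feasibility problem over the scaled-space Delaunay
candidate pairs — and true corners are the scaled-Delaunay circumcentres
inside the domain. Default study conditions: 60 cells at 64³ voxels,
jitter 0.5, anisotropy (2, 1, 1) for the anisotropic condition.

The dome generator emulates the SAM's layered organisation with a columnar
construction: anchor directions on a sphere by farthest-point sampling,
L1/L2/inner seeds on each anchor's inward radius at depths 0.10/0.32/0.50
of the radius (±0.3 voxel jitter). The domain is a full ball rather than a
cut hemisphere: any planar cut would expose the deeper layers to the
background at the cut — exactly the part of a real acquisition the layered
reconstruction does not use — whereas the ball with radial columns and
bounded anchor coverage *guarantees* the stratification (every L1 region
touches background, L2 regions touch only L1), making the recorded layer
truth exact. This needs roughly 24 or more L1 anchors at the default
geometry; n_L2 ≤ n_L1 keeps every L2 column shielded. Defaults: 32 + 32 + 8
cells at 64³.

The degradation operator relabels boundary voxels to a neighbouring cell
(never background), rejecting swaps that would disconnect the donor region,
as a model of segmentation noise.

What the generators do *not* emulate: curved (non-planar) walls, cell-size
gradients, division-plane correlations, fluorescence noise or segmentation
artifacts beyond the voxel discretization and the explicit degradation
operator. Passing tests therefore demonstrate correctness of the
reconstruction machinery on tessellation-like tissue, not robustness to
every real-microscopy failure mode.

## Numerical choices and limitations

Degenerate adjacency tetrahedra fall back to centroid dual vertices
(logged). Flat triangles get eccentricity 1. Voxel centres exactly on a
face are perturbed by +1e-6 voxel before the parity test. Determinism:
every stochastic component takes one integer seed; the pipeline derives the
mesh optimizer's seed from the config seed, and two runs with equal seeds
produce byte-identical meshes and reports.

Known limitations: ambiguous junctions where five or more cells converge
are resolved by the energy alone (lineage information across time points,
which could disambiguate them, is out of scope), so a few mesh corners have
no image counterpart and remain unpinned; wall areas are uncorrected
staircase counts; the L1 2.5D dual closes boundary cell polygons with
straight rim segments; the exterior-clipping of very obtuse boundary
triangles clamps their circumcircle centres into the triangle before
projection; and test problem sizes (25–72 cells, 32³–64³) are chosen so the
full pipeline and its property checks run comfortably on one CPU — the
algorithms themselves scale to the ~1000-cell regime of real acquisitions,
at proportionally longer annealing times.
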