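import numpy as np
import pytest

from tissuemesh import draco
from tissuemesh.image_adjacency import (binary_isosurface,
                                        extract_adjacencies)
from tissuemesh.synthetic import (generate_layered_dome,
                                  generate_voronoi_tissue)


@pytest.fixture(scope="session")
def voronoi_tissue():
    """Small anisotropic Voronoi tissue with exact ground truth."""
    return generate_voronoi_tissue(n_cells=25, resolution=48,
                                   anisotropy=(1.6, 1, 1), jitter=0.5,
                                   rng_seed=11)


@pytest.fixture(scope="session")
def voronoi_adj(voronoi_tissue):
    return extract_adjacencies(voronoi_tissue.image)


@pytest.fixture(scope="session")
def dome_tissue():
    """Small layered dome with exact layer truth."""
    return generate_layered_dome(n_L1=24, n_L2=24, n_inner=4,
                                 resolution=48, rng_seed=7)


@pytest.fixture(scope="session")
def dome_adj(dome_tissue):
    return extract_adjacencies(dome_tissue.image)


@pytest.fixture(scope="session")
def dome_iso(dome_tissue):
    return binary_isosurface(dome_tissue.image)


@pytest.fixture(scope="session")
def cleaned_complex(voronoi_tissue, voronoi_adj):
    T = draco.delaunay_adjacency(voronoi_adj.barycenters)
    return draco.clean_exterior(T, voronoi_adj, image=voronoi_tissue.image)


@pytest.fixture(scope="session")
def dome_dual(dome_tissue, dome_adj, dome_iso):
    T = draco.delaunay_adjacency(dome_adj.barycenters)
    T = draco.clean_exterior(T, dome_adj, image=dome_tissue.image)
    return draco.dual_geometry(T, dome_adj, isosurface=dome_iso)


@pytest.fixture(scope="session")
def dome_opt_mesh(dome_tissue, dome_adj, dome_iso):
    """Star mesh of the annealed adjacency complex of the small dome."""
    from tissuemesh.stem import star_triangulate
    T = draco.delaunay_adjacency(dome_adj.barycenters)
    T = draco.clean_exterior(T, dome_adj, image=dome_tissue.image)
    T = draco.optimize_adjacency(
        T, dome_adj, schedule=draco.AnnealingSchedule(cycles=2, rng_seed=1))
    D = draco.dual_geometry(T, dome_adj, isosurface=dome_iso)
    return star_triangulate(D)


@pytest.fixture(scope="session")
def dome_star_mesh(dome_dual):
    from tissuemesh.stem import star_triangulate
    return star_triangulate(dome_dual)


def single_tet_complex(positions=None):
    """A full simplicial complex of one tetrahedron on labels 2..5."""
    from tissuemesh.complex_core import simplicial_from_tetrahedra
    if positions is None:
        positions = {2: np.array([0.0, 0, 0]), 3: np.array([1.0, 0, 0]),
                     4: np.array([0.0, 1, 0]), 5: np.array([0.0, 0, 1])}
    return simplicial_from_tetrahedra([(2, 3, 4, 5)], positions=positions)
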