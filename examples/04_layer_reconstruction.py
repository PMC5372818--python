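"""Reconstruct only the epidermal layers by simplex aggregation.

The L1/L2 layers of the meristem are anticlinally separated, so their
adjacency complex can be built greedily from image-extracted tetrahedra
(best image support first) instead of annealing — and an L1-only triangle
complex dualizes to a 2.5D surface mesh with one polygonal face per cell.
"""

from tissuemesh import (aggregate_layer_complex, extract_adjacencies,
                        generate_layered_dome, layer_assignment)
from tissuemesh.complex_core import simplex_labels

tissue = generate_layered_dome(rng_seed=0)
adj = extract_adjacencies(tissue.image)
layers = layer_assignment(adj)
n_l1 = sum(1 for v in layers.values() if v == "L1")
n_l2 = sum(1 for v in layers.values() if v == "L2")
print(f"layers: {n_l1} L1 cells, {n_l2} L2 cells")

C = aggregate_layer_complex(adj, mode="L1L2")
tets = simplex_labels(C, 3)
covered = {v for t in tets for v in t}
print(f"L1L2 aggregation: {len(tets)} tetrahedra covering "
      f"{len(covered)} of {n_l1 + n_l2} layer cells")

S = aggregate_layer_complex(adj, mode="L1")
print(f"L1 surface: {len(simplex_labels(S, 2))} adjacency triangles "
      f"(dualizes to a 2.5D polygonal mesh, one face per L1 cell)")
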