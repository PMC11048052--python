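"""Synthesize pseudo-spots and build the random-projection-forest spot graph.

Pseudo-spots sum the expression of 2-8 randomly drawn cells, so each carries
an exact ground-truth type composition; the forest adjacency connects spots
that repeatedly co-occur in random projection tree leaves.
"""

import numpy as np

from gtadc import forest_adjacency, generate_pseudospots, normalize
from gtadc.simulate import SimulationConfig, simulate_reference

sim = SimulationConfig(k=3, cells_per_type=50, n_genes=400, markers_per_type=10, seed=1)
reference, labels, _ = simulate_reference(sim)

spots = generate_pseudospots(reference, labels, n_spots=200, seed=2)
counts = np.array([len(m) for m in spots.members])
print(f"{spots.expression.n_rows} pseudo-spots, "
      f"member cells per spot: min {counts.min()}, mean {counts.mean():.1f}, "
      f"max {counts.max()}")
print("first spot truth:",
      {t: round(float(v), 2) for t, v in zip(labels.types, spots.truth.values[0])})

features = normalize(spots.expression).values
adjacency = forest_adjacency(features, T=10, leaf_size=20, seed=3)
A = adjacency.toarray()
print(f"adjacency: {A.shape[0]} nodes, "
      f"{(A > 0).sum() // 2} undirected edges, weights on the 1/10 grid")
print(f"mean edge weight {A[A > 0].mean():.2f}")
# Edge weights are leaf co-occurrence frequencies over 10 trees: 1.0 means two
# spots landed together in every tree (near-identical expression profiles).
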