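"""Diffused node-pair similarity between two small networks.

Builds a 4-node path and a 4-node cycle, seeds the diffusion with a
sequence-similarity prior that supports the identity pairing, and prints
the resulting similarity matrix.  The triple-matrix-product kernel is
checked against the explicit Kronecker formulation on the stacked
vector: the two are the same operator, so they agree to machine
precision.
"""

import numpy as np

from ppialign import ElementalSimilarity, Network, isorank_iterate, kronecker_oracle

path = Network.from_edges("path", [("p0", "p1"), ("p1", "p2"), ("p2", "p3")])
cycle = Network.from_edges("cycle", [("c0", "c1"), ("c1", "c2"),
                                     ("c2", "c3"), ("c3", "c0")])

# prior: each path node resembles its same-index cycle node (score 1),
# everything else 0 — the sequence-similarity stand-in
H = ElementalSimilarity(np.eye(4))

X = isorank_iterate(path, cycle, H, alpha=0.8, iterations=20)
oracle = kronecker_oracle(path, cycle, H, alpha=0.8, iterations=20)

np.set_printoptions(precision=4, suppress=True)
print("similarity matrix X (rows = path nodes, columns = cycle nodes):")
print(X.X)
print(f"\ntotal similarity mass: {X.X.sum():.12f}  (kept at 1 by design)")
print(f"max |matrix kernel - Kronecker oracle|: {np.abs(X.X - oracle.X).max():.2e}")
print("\nEach entry is the diffused evidence that a path node corresponds to a")
print("cycle node; the diagonal dominates because the prior plus the shared")
print("neighbourhood structure both point at the identity pairing.")
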