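"""The three matching heuristics against the exact optimum.

Generates a random 6x7 score matrix and extracts a one-to-one matching
with the greedy 1/2-approximation, the fixed-increment auction, and the
adaptive epsilon-scaling auction, comparing each weight with the
brute-force enumeration optimum.
"""

import numpy as np

from ppialign import (adaptive_auction_match, auction_match,
                      brute_force_optimal, greedy_match)

rng = np.random.default_rng(7)
X = rng.random((6, 7))

opt = brute_force_optimal(X)
print(f"optimal weight (enumeration over all injections): {opt.weight:.4f}\n")

for m in (greedy_match(X),
          auction_match(X, epsilon=1 / 7, scale=10**6),
          adaptive_auction_match(X)):
    ratio = m.weight / opt.weight
    print(f"{m.method:18s} weight {m.weight:.4f}  ({100 * ratio:.1f}% of optimal, "
          f"{len(m)} pairs)")

print("\nGreedy is guaranteed >= 50% of the optimum; the auctions typically land")
print("within a few percent of it, and the adaptive variant pads unmatched rows")
print("so the matching always reaches maximum cardinality.")
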