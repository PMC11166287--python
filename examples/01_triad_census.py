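"""Triadic census of a small regulatory motif set, with an incremental update.

Builds a 6-gene network containing a feed-forward loop and a 3-cycle,
prints its connected-triad census, then adds one edge and shows that the
O(Delta) incremental update agrees with a full recount.
"""

import numpy as np

from grnbool.netcore import (
    TRIAD_LABELS,
    DirectedNetwork,
    apply_edge_mutation,
    compute_topology_features,
    count_triads,
)

adj = np.zeros((6, 6), dtype=int)
for r, t in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (5, 3)]:
    adj[r, t] = 1  # feed-forward loop on genes 0-2, cycle on genes 3-5
net = DirectedNetwork(adj)

census = count_triads(net)
print("connected triads:")
for label, count in zip(TRIAD_LABELS, census.counts):
    if count:
        print(f"  {label}: {count}")
# 030T is the feed-forward loop, 030C the three-gene cycle.

apply_edge_mutation(net, census, (2, 3), add=True)
fresh = count_triads(net)
print("incremental census equals recount after adding G3->G4:",
      bool(np.array_equal(census.counts, fresh.counts)))

features = compute_topology_features(net)
print(f"density {features.density:.3f}; census mass on 030T/030C:",
      features.census_norm[TRIAD_LABELS.index('030T')],
      features.census_norm[TRIAD_LABELS.index('030C')])
# The normalized census is the topology fingerprint compared against
# reference networks during optimisation.
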