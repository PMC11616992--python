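"""Degree and betweenness centrality on the two classic illustration graphs.

A star hub is a local 'hub' (maximal degree centrality); the bridge between
two cliques is a global 'connector' (maximal betweenness centrality).  In a
protein residue network the same two roles distinguish ordered regions from
the residues that carry allosteric communication between them.
"""

import numpy as np

from lspnet import betweenness_centrality, degree_centrality, generate_toy_graph

hub = generate_toy_graph("hub_star", n_leaves=8)
dc = degree_centrality(hub)
print(f"star hub degree centrality: {dc[0]:.0f}  (leaves: {dc[1]:.0f})")

bridged = generate_toy_graph("bridged_cliques", k1=3, k2=3)
bc = betweenness_centrality(bridged, length_transform="unit")
print(f"bridge-endpoint betweenness: {bc[0]:.0f} and {bc[3]:.0f}; all others: {np.delete(bc, [0, 3]).max():.0f}")
print()
print("The hub touches every leaf (DC = 8) but lies on no inter-clique path;")
print("each bridge endpoint carries all 6 shortest paths between the cliques' other members.")
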