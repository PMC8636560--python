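"""Directed trophic networks and PageRank hub detection.

Edges run predator -> prey; weights are either mean standardized-read
proportions ("reads") or appearance frequencies ("frequency"). PageRank on
this graph concentrates on prey eaten by many groups — trophic hubs.
"""

import trophonet as tn
from trophonet.io import read_node_classes

config = tn.five_guild_demo_config(seed=1)
table, taxonomy, metadata, truth = tn.simulate_dataset(config)
profiles, _ = tn.compute_profiles(table, taxonomy, metadata, tn.default_rules())
summaries = [
    s
    for s in tn.summarize_group(profiles, tn.grouping_by_metadata(metadata))
    if s.group_key != "water"
]

for mode in ("reads", "frequency"):
    net = tn.build_network(summaries, mode=mode, node_classes=read_node_classes())
    scores = tn.pagerank(net, damping=0.85)
    hubs = tn.rank_hubs(scores, top_n=3)
    print(f"{mode} mode: {net.graph.number_of_nodes()} nodes, "
          f"{net.graph.number_of_edges()} edges")
    for h in hubs:
        print(f"  hub {h:<18s} pagerank {scores.scores[h]:.3f} "
              f"(role {net.graph.nodes[h]['role']})")

print(
    f"\nThe planted universal prey ({truth.hub_category}) tops both rankings:"
    "\nit receives an edge from every predator group, exactly how calanoids"
    "\nemerge as the central node of a plankton food web."
)
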