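"""Strongly connected component extraction and hub-gene topology.

The synthetic reference-scale network (398 genes, 622 directed interactions)
contains exactly one nontrivial SCC of 60 genes and 158 interactions with a
planted hub; NetworkAnalyzer-style metrics identify it.
"""

import methyltraj as mt
from methyltraj.datasets import reference_like_network
from methyltraj.network import build_network, extract_scc

edges, planted = reference_like_network()
net = build_network(edges)
print(f"full network: {len(net.nodes)} genes, {net.n_edges} interactions")

scc = extract_scc(net)
print(f"SCC: {len(scc.nodes)} genes, {scc.n_edges} interactions "
      f"(matches planted: {set(scc.nodes) == planted})")

metrics = mt.topology_metrics(scc)
hub = mt.rank_hub_genes(metrics)[0]
row = metrics.loc[hub]
print(f"top hub: {hub}  in = {int(row.in_degree)}, out = {int(row.out_degree)}, "
      f"betweenness = {row.betweenness:.3f}, "
      f"CC = {row.clustering_coefficient:.3f}, "
      f"neighborhood connectivity = {row.neighborhood_connectivity:.2f}")
# The hub regulates 20 genes and is regulated by 7; its sparse neighborhood
# (low clustering coefficient) marks it as a broadcast regulator rather than
# a member of a tight clique.
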