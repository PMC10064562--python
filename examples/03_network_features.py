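"""Build the mutation co-occurrence network, find hubs, read off features.

Run:  python examples/03_network_features.py
"""

from pahpheno import (build_network, connectivity_report, find_hub_nodes,
                      generate_worked_fixture, hub_distances, node_attributes,
                      parse_hgvs_cdna)

db = generate_worked_fixture()
net = build_network(db)
hubs = find_hub_nodes(net)

print(f"cohort: {len(db)} patients, {len(db.mutation_index)} distinct mutations")
print(f"network: {net.graph.number_of_edges()} co-occurrence edges; "
      f"total edge weight {net.total_edge_weight()} (= patient count)")
rep = connectivity_report(net)
print(f"components: {rep.sizes} (node counts)")
print(f"hubs: cPKU={hubs.hub_cpku.label}  mPKU={hubs.hub_mpku.label}  "
      f"MHP={hubs.hub_mhp.label}")
print("(each hub maximises the number of patients of its class carrying it)")

m = parse_hgvs_cdna("c.1301C>A")
d = hub_distances(net, m, hubs)
a = node_attributes(net, m)
print(f"\n{m.label}: hub distances (cPKU, mPKU, MHP) = {d.tolist()}")
print(f"  degree={a[0]:g}  betweenness={a[1]:.4f}  pagerank={a[2]:.4f}  "
      f"closeness={a[3]:.4f}  eccentricity={a[4]:g}")
print("(the 3 distances + 5 attributes are the 8 graph features per allele)")
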