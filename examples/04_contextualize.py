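"""Build a MID-similarity network and rank nearest unknown neighbors.

Metabolites in the same pathway inherit related labeling patterns, so
cosine similarity between corrected MIDs clusters them; unknown
features attached to annotated ones inherit biological context.
"""

import itertools

import numpy as np

import isocontext as ic

config = ic.benchmark_config(seed=1)
features, samples, truth = ic.simulate_experiment(config)
groups = ic.detect_groups(features, samples, ic.TracerDef.from_name("13C"),
                          ic.DetectionParams(), "cond1")
estimates = ic.estimate_mids(groups, features, samples)
# mark half the nodes annotated to show the unknown-neighbor ranking
names = {e.group_id: f"metab_{i}" for i, e in enumerate(estimates) if i % 2 == 0}
mids = ic.estimates_to_mid_table(estimates, display_names=names)

net = ic.build_network(mids, threshold=0.9, metric="cosine", combine="mean")
print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges "
      f"at cosine >= 0.9")

base_to_comp = {fid: n for n, fid in truth.base_features.items()}
node_group = {e.group_id: truth.pathway_groups[base_to_comp[e.base_feature_id]]
              for e in estimates if e.base_feature_id in base_to_comp}
flags = [node_group[e.node_a] == node_group[e.node_b] for e in net.edges]
print(f"{100 * np.mean(flags):.0f}% of edges connect same-pathway compounds")

within, cross = [], []
for a, b in itertools.combinations(net.nodes, 2):
    sim = ic.combined_similarity(a, b)
    (within if node_group[a.node_id] == node_group[b.node_id]
     else cross).append(sim)
print(f"median similarity: {np.median(within):.3f} within pathway groups "
      f"vs {np.median(cross):.3f} across")

annotated = next(n for n in net.nodes if n.annotated)
neighbors = ic.nearest_unknown_neighbors(net, annotated.node_id, k=3)
print(f"nearest unknown neighbors of {annotated.display_name}: "
      + ", ".join(f"{nid} ({sim:.3f})" for nid, sim in neighbors))
# These unknowns share the annotated metabolite's labeling pattern and are
# the first candidates for being pathway neighbors.
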