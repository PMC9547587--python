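"""Overlap-enrichment network and consensus hub miRNAs.

Scores every miRNA pair for overlap of their disease sets (one-sided
Fisher exact test over the disease universe), keeps the BH-significant
top-k edges weighted by odds ratio, then ranks nodes by seven weighted
centrality measures and reports the consensus hubs (top-T lists of at
least 5 measures).
"""

from mirdmap import (
    FixtureSpec,
    build_db,
    build_graph,
    build_network,
    centrality_suite,
    consensus,
    epc,
    generate,
    merge_on_key,
)

spec = FixtureSpec(n_mirnas=80, n_genes=120, n_diseases=60,
                   clique_sizes=(6, 5, 5), seed=6)
mg, gd, truth = generate(spec)
merged, _ = merge_on_key(mg, gd)
db = build_db(merged)

result = build_network(db, mode="mirna", top_k=100, alpha=0.05)
print(f"scored {result.n_tests} miRNA pairs; "
      f"{result.n_significant} significant at q <= 0.05; "
      f"kept top {len(result.edges)} edges over {len(result.node_names())} nodes")

g = build_graph(result.edges)
report = consensus(centrality_suite(g), top_t=10, min_agreement=5)
members = {m for cl in truth.cliques for m in cl}
print(f"\nconsensus hubs (in top-10 of >=5 of 7 centrality measures):")
print("node\tagreement\tin planted clique")
for v in report.consensus:
    print(f"{v}\t{report.agreement[v]}\t{v in members}")

scores = epc(g, reps=1000, seed=42)
top_epc = sorted(scores, key=lambda v: -scores[v])[:3]
print("\ntop-3 by edge-percolation centrality (mean connectivity):")
for v in top_epc:
    print(f"  {v}: {scores[v]:.2f}")
# Hubs mostly fall inside the planted cliques: block members share
# near-identical disease sets and dominate degree-like measures, while
# path-based measures (betweenness, closeness) can promote background
# nodes that bridge otherwise separate parts of the network.
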