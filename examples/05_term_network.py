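"""Cluster-term network: de-duplication and gene-sharing edges.

Terms sharing > 98% of their genes with a better-ranked term in the
same cluster are discarded; surviving terms connect when they share
> 40% of genes (denominator: the smaller set) and attach to their
clusters with -log10 p weights.  The export feeds external layout
tools (Gephi/ForceAtlas2).
"""

import tempfile
from pathlib import Path

import numpy as np

from crossregen import build_network, dedupe_terms, export_network

rng = np.random.default_rng(0)
genes = [f"g{i}" for i in range(200)]
terms = []
for i in range(12):
    size = int(rng.integers(20, 60))
    terms.append((f"term{i}", set(rng.choice(genes, size, replace=False)),
                  float(rng.uniform(1e-6, 0.05))))
# a near-duplicate of term0 that the 98% rule should remove
terms.append(("term0_copy", terms[0][1] | {"g_extra"}, 0.04))

kept = dedupe_terms(terms, share_cut=0.98)
print(f"{len(terms)} terms -> {len(kept)} after 98% de-duplication "
      f"(removed: {sorted(set(t[0] for t in terms) - set(k[0] for k in kept))})")

g = build_network({"cluster5": kept}, edge_cut=0.4)
term_edges = [e for e in g.edges if not any(n.startswith('cluster:') for n in e)]
print(f"network: {g.number_of_nodes()} nodes, {len(term_edges)} term-term edges")
with tempfile.TemporaryDirectory() as td:
    export_network(g, Path(td) / "net.graphml", Path(td) / "net.gexf")
    print("exported GraphML + GEXF for external layout")
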