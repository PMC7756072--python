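"""Cluster-term network: de-duplicate near-identical terms, connect
terms by gene sharing, attach terms to their clusters, export for
external layout (Gephi/ForceAtlas2 consume the GEXF/GraphML)."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


def sharing_fraction(a: set, b: set, mode: str = "min") -> float:
    """|A ∩ B| / min(|A|,|B|) (default) or Jaccard."""
    inter = len(a & b)
    if mode == "min":
        denom = min(len(a), len(b))
    elif mode == "jaccard":
        denom = len(a | b)
    else:
        raise ValueError(f"unknown sharing mode {mode!r}")
    return inter / denom if denom else 0.0


def dedupe_terms(terms, share_cut: float = 0.98, mode: str = "min"):
    """Drop terms sharing more than ``share_cut`` of their genes with a
    better term.

    ``terms`` is a list of (name, gene set, p).  Terms are visited in
    keep-priority order (smaller p, then larger set, then name); a term
    is discarded if its sharing fraction with any already retained term
    exceeds the cut (strict >).
    """
    ordered = sorted(terms, key=lambda t: (t[2], -len(t[1]), t[0]))
    kept = []
    for name, genes, p in ordered:
        if any(sharing_fraction(genes, kg, mode) > share_cut for _, kg, _ in kept):
            continue
        kept.append((name, set(genes), p))
    return kept


def build_network(
    cluster_terms: dict[str, list],
    edge_cut: float = 0.4,
    share_cut: float = 0.98,
    mode: str = "min",
    dedupe: bool = True,
) -> nx.Graph:
    """Build the term/cluster graph.

    ``cluster_terms`` maps cluster name to a list of (term, gene set, p)
    of its significant terms.  Per cluster, near-duplicate terms are
    removed first (98% rule).  Term-term edges are drawn when the
    sharing fraction strictly exceeds ``edge_cut`` and carry it as
    weight; each term also attaches to every cluster it is significant
    in, weighted by -log10 p.  Node size is -log10 of the best
    (smallest) p across clusters.
    """
    g = nx.Graph()
    term_genes: dict[str, set] = {}
    term_best_p: dict[str, float] = {}
    for cluster, terms in sorted(cluster_terms.items()):
        kept = dedupe_terms(terms, share_cut, mode) if dedupe else [
            (n, set(s), p) for n, s, p in terms
        ]
        anchor = f"cluster:{cluster}"
        g.add_node(anchor, kind="cluster")
        for name, genes, p in kept:
            term_genes.setdefault(name, set()).update(genes)
            term_best_p[name] = min(term_best_p.get(name, 1.0), p)
            g.add_edge(anchor, name, weight=float(-np.log10(max(p, 1e-300))))
    for name in term_genes:
        g.add_node(name, kind="term", p=term_best_p[name],
                   size=float(-np.log10(max(term_best_p[name], 1e-300))))
    names = sorted(term_genes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            f = sharing_fraction(term_genes[a], term_genes[b], mode)
            if f > edge_cut:
                g.add_edge(a, b, weight=float(f))
    return g


def export_network(g: nx.Graph, graphml_path=None, gexf_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if gexf_path is not None:
        nx.write_gexf(g, gexf_path)
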