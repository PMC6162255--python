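"""Assembly of the DEP protein-protein interaction network.

Seed nodes are DEPs annotated to at least one enriched term; neighbors
from the interaction edge list are retained only when they are DEPs
themselves or are annotated to one of the selected terms. Nodes carry
log2 fold change, DEP status and the enriched-term group labels used to
organize the model; edges keep their source-database provenance.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .enrichment import AnnotationSet

__all__ = ["read_edge_list", "build_network", "network_to_frames"]


def read_edge_list(path) -> pd.DataFrame:
    """Parse a tab-delimited interaction list: id_a, id_b, source_db.

    Malformed rows (fewer than two fields) are skipped; the skipped
    count is attached as ``df.attrs['n_skipped']``.
    """
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                skipped += 1
                continue
            rows.append(
                {
                    "id_a": parts[0],
                    "id_b": parts[1],
                    "source_db": parts[2] if len(parts) > 2 else "unknown",
                }
            )
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "source_db"])
    df.attrs["n_skipped"] = skipped
    return df


def build_network(
    protein_results: pd.DataFrame,
    enriched_terms: pd.DataFrame,
    edges: pd.DataFrame,
    annotations: list[AnnotationSet],
) -> nx.Graph:
    """Build the DEP interaction model as an undirected graph.

    ``protein_results`` comes from the differential test (columns
    protein_id, protein_log2fc, is_dep); ``enriched_terms`` from
    enrich_terms (rows with significant == True select the terms);
    ``edges`` is an (id_a, id_b, source_db) frame. Self-loops and
    duplicate edges are dropped; the result is invariant to edge row
    order.
    """
    ann_by_term = {a.term_id: a.members for a in annotations}
    if len(enriched_terms):
        selected = [
            t
            for t in enriched_terms.loc[
                enriched_terms.get("significant", False), "term_id"
            ]
            if t in ann_by_term
        ]
    else:
        selected = []
    term_members: dict[str, frozenset[str]] = {t: ann_by_term[t] for t in selected}

    deps = set(protein_results.loc[protein_results["is_dep"], "protein_id"])
    lfc = protein_results.set_index("protein_id")["protein_log2fc"].to_dict()

    def labels_of(node: str) -> tuple[str, ...]:
        labs = tuple(sorted(t for t, mem in term_members.items() if node in mem))
        return labs if labs else ("unassigned",)

    seeds = {d for d in deps if labels_of(d) != ("unassigned",)}
    if not term_members:
        seeds = set(deps)  # no enrichment selection: all DEPs seed the model

    def qualifies(node: str) -> bool:
        return node in deps or any(node in mem for mem in term_members.values())

    clean = edges.loc[edges["id_a"] != edges["id_b"]]
    # pass 1: node set = seeds plus qualifying first neighbors of seeds
    nodes = set(seeds)
    for row in clean.itertuples(index=False):
        a, b = row.id_a, row.id_b
        if a in seeds and b not in nodes and qualifies(b):
            nodes.add(b)
        if b in seeds and a not in nodes and qualifies(a):
            nodes.add(a)

    # pass 2: induced edges among retained nodes, deduplicated
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for row in clean.sort_values(["id_a", "id_b", "source_db"]).itertuples(index=False):
        a, b = row.id_a, row.id_b
        if a not in nodes or b not in nodes:
            continue
        if g.has_edge(a, b):
            prov = set(g.edges[a, b]["source_db"].split(";"))
            prov.add(row.source_db)
            g.edges[a, b]["source_db"] = ";".join(sorted(prov))
        else:
            g.add_edge(a, b, source_db=row.source_db)

    for n in g.nodes:
        g.nodes[n]["log2fc"] = float(lfc.get(n, 0.0))
        g.nodes[n]["is_dep"] = n in deps
        g.nodes[n]["groups"] = ";".join(labels_of(n))
    return g


def network_to_frames(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a network to (node attribute table, SIF-style edge table)."""
    nodes = pd.DataFrame(
        [
            {
                "protein_id": n,
                "log2fc": d.get("log2fc", 0.0),
                "is_dep": d.get("is_dep", False),
                "groups": d.get("groups", "unassigned"),
            }
            for n, d in sorted(g.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"id_a": a, "id_b": b, "source_db": d.get("source_db", "unknown")}
            for a, b, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
        columns=["id_a", "id_b", "source_db"],
    )
    return nodes, edges
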