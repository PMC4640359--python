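"""The "disrupted network": a pruned interaction subnetwork around common-DE genes.

Starting from a protein interactome (edge-list TSV; extreme hubs such as
ubiquitin C removed by a degree cutoff), the subnetwork is seeded with the
query set of commonly differentially expressed genes, expanded to their
interaction partners, and pruned: a non-query protein is kept only if it
interacts with at least two query proteins and retains degree >= 2, and
query proteins are kept while they have at least one interaction.  Pruning
is iterated to a fixpoint, which makes the construction idempotent and
independent of node iteration order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import DataError

logger = logging.getLogger(__name__)

DEFAULT_HUB_CUTOFF = 5000

QUERY = "query"
DE_ONE = "de_one_dataset"
PARTNER = "partner"


@dataclass
class DisruptedNetwork:
    graph: nx.Graph
    node_label: dict[str, str]
    stats: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def _strip_db_prefix(token: str) -> str:
    # PSI-MITAB-style identifiers carry a "db:" prefix (e.g. uniprotkb:P04637)
    return token.split(":", 1)[1] if ":" in token else token


def load_interactome(
    path: str | Path, hub_degree_cutoff: int = DEFAULT_HUB_CUTOFF
) -> nx.Graph:
    """Load a two-column edge list into a simple undirected graph.

    Self-loops and duplicate (unordered) edges are dropped with a logged
    count.  Every node whose degree in the cleaned graph exceeds
    ``hub_degree_cutoff`` is then removed with its incident edges — the
    treatment real analyses apply to ubiquitin C and similar mega-hubs.
    """
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise DataError(f"{path}:{lineno}: malformed edge line {line!r}")
            a, b = _strip_db_prefix(parts[0]), _strip_db_prefix(parts[1])
            if {a, b} == {"protein_a", "protein_b"}:
                continue  # header row
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_self or n_dup:
        logger.info("load_interactome: dropped %d self-loops, %d duplicate edges", n_self, n_dup)

    hubs = [v for v, d in g.degree if d > hub_degree_cutoff]
    if hubs:
        logger.info(
            "load_interactome: removed %d hub(s) with degree > %d: %s",
            len(hubs), hub_degree_cutoff, sorted(hubs)[:10],
        )
        g.remove_nodes_from(hubs)
    if g.number_of_nodes() == 0:
        raise DataError(f"{path}: interactome empty after hub filtering")
    return g


def build_disrupted(
    interactome: nx.Graph,
    query: Iterable[str],
    de_either: Iterable[str] | None = None,
    force_include: Iterable[str] = (),
    single_pass: bool = False,
) -> DisruptedNetwork:
    """Construct the pruned query-seeded subnetwork.

    Steps: (1) candidates = query plus all their interaction partners;
    (2) induced subgraph; (3) drop non-query nodes with fewer than two query
    neighbours; (4) iteratively drop non-query nodes of degree < 2 and
    query nodes of degree 0 until nothing changes (re-checking the two-query-
    neighbour rule as the graph shrinks), unless ``single_pass`` requests one
    sweep only.  Nodes are then labelled query / de_one_dataset / partner.

    ``force_include`` nodes (e.g. a reference receptor) are added back with
    their edges to retained nodes after pruning.
    """
    query = set(query)
    if not query:
        raise DataError("query set is empty")
    present = query & set(interactome.nodes)
    missing = query - present
    if missing:
        logger.info(
            "build_disrupted: %d/%d query ids absent from the interactome",
            len(missing), len(query),
        )
    if not present:
        raise DataError("no query id occurs in the interactome")

    candidates = set(present)
    for q in present:
        candidates.update(interactome.neighbors(q))
    sub = interactome.subgraph(candidates).copy()

    def doomed(g: nx.Graph) -> set[str]:
        out = set()
        for v in g.nodes:
            deg = g.degree[v]
            if v in query:
                if deg == 0:
                    out.add(v)
            else:
                q_neigh = sum(1 for u in g.neighbors(v) if u in query)
                if q_neigh < 2 or deg < 2:
                    out.add(v)
        return out

    drop = doomed(sub)
    sub.remove_nodes_from(drop)
    if not single_pass:
        while True:
            drop = doomed(sub)
            if not drop:
                break
            sub.remove_nodes_from(drop)

    for v in set(force_include):
        if v in interactome and v not in sub:
            sub.add_node(v)
            sub.add_edges_from((v, u) for u in interactome.neighbors(v) if u in sub)

    if sub.number_of_nodes() == 0:
        logger.warning("build_disrupted: pruning removed every node; network is empty")

    de_either = set(de_either or ())
    labels: dict[str, str] = {}
    for v in sub.nodes:
        if v in query:
            labels[v] = QUERY
        elif v in de_either:
            labels[v] = DE_ONE
        else:
            labels[v] = PARTNER
    nx.set_node_attributes(sub, labels, "node_label")

    n_nodes = sub.number_of_nodes()
    n_query = sum(1 for v in labels.values() if v == QUERY)
    n_de = sum(1 for v in labels.values() if v == DE_ONE)
    stats = {
        "n_nodes": n_nodes,
        "n_edges": sub.number_of_edges(),
        "n_query_with_interactions": n_query,
        "n_de_either": n_de,
        "frac_de": (n_query + n_de) / n_nodes if n_nodes else 0.0,
    }
    return DisruptedNetwork(graph=sub, node_label=labels, stats=stats)


def apply_id_mapping(genes: Iterable[str], mapping: Mapping[str, str]) -> list[str]:
    """Translate gene ids to protein ids with a verbatim two-column mapping;
    unmapped ids pass through unchanged."""
    return [mapping.get(g, g) for g in genes]


def read_id_mapping(path: str | Path) -> dict[str, str]:
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: malformed mapping line {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def write_network(net: DisruptedNetwork, edge_path: str | Path, graphml_path: str | Path,
                  stats_path: str | Path) -> None:
    with open(edge_path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
    nx.write_graphml(net.graph, graphml_path)
    Path(stats_path).write_text(json.dumps(net.stats, indent=1))
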