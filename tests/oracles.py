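"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: the
hypergeometric tail is computed by exhaustive enumeration of draws, and the
disrupted-network construction by a plain set-based one-node-at-a-time
pruner with no networkx.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations


def hypergeom_tail_by_enumeration(k: int, universe: int, n_marked: int, n_drawn: int) -> float:
    """P(|draw ∩ marked| >= k) by enumerating every C(universe, n_drawn) draw."""
    items = list(range(universe))
    marked = set(items[:n_marked])
    hits = total = 0
    for draw in combinations(items, n_drawn):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def disrupted_by_bruteforce(
    edges: set[frozenset], query: set[str]
) -> tuple[set[str], set[frozenset]]:
    """Reference construction of the pruned query-seeded subnetwork.

    Candidates are the query plus all their partners; nodes violating the
    retention rule (non-query: >= 2 query neighbours and degree >= 2;
    query: degree >= 1) are deleted one at a time until none violate it.
    The maximal feasible subset is unique, so deletion order is irrelevant.
    """
    adj: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    present = query & set(adj)
    nodes = set(present)
    for q in present:
        nodes |= adj[q]

    changed = True
    while changed:
        changed = False
        for v in sorted(nodes):
            neigh = adj[v] & nodes
            if v in query:
                ok = len(neigh) >= 1
            else:
                ok = len(neigh) >= 2 and len(neigh & query) >= 2
            if not ok:
                nodes.discard(v)
                changed = True
                break
    kept_edges = {
        frozenset((a, b)) for a in nodes for b in adj[a] & nodes if a < b
    }
    return nodes, kept_edges
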