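"""Compound-compound shared-target network and community structure.

Nodes are compounds (NP or CT) with at least one exact binding value below
100 nM; an edge joins two compounds sharing at least one such target, with
weight equal to the shared-target count.  Communities are found by
multilevel (Louvain) modularity optimization on the weighted graph, which
handles disconnected networks naturally, and each community is characterized
by its compound-class composition (Fisher exact enrichment) and the protein
families of its targets.
"""

from __future__ import annotations

import random
from itertools import combinations

import igraph as ig
import pandas as pd
from scipy import stats

from .errors import DataError
from .evidence import Interaction


def qualifying_targets(
    interactions: list[Interaction], threshold_nM: float = 100.0
) -> dict[str, set[str]]:
    """compound -> set of targets bound with an exact value < threshold."""
    out: dict[str, set[str]] = {}
    for i in interactions:
        if i.best_exact_value_nM is not None and i.best_exact_value_nM < threshold_nM:
            out.setdefault(i.compound_id, set()).add(i.target_id)
    return out


def build_compound_graph(
    interactions: list[Interaction],
    classes: dict[str, str],
    threshold_nM: float = 100.0,
) -> ig.Graph:
    """Weighted shared-target compound graph at the affinity threshold."""
    targets_of = qualifying_targets(interactions, threshold_nM)
    compounds = sorted(targets_of)
    index = {c: i for i, c in enumerate(compounds)}
    edges, weights = [], []
    for c1, c2 in combinations(compounds, 2):
        w = len(targets_of[c1] & targets_of[c2])
        if w:
            edges.append((index[c1], index[c2]))
            weights.append(w)
    g = ig.Graph(n=len(compounds), edges=edges)
    g.vs["name"] = compounds
    g.vs["compound_class"] = [classes[c] for c in compounds]
    g.es["weight"] = weights
    return g


def detect_communities(graph: ig.Graph, seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain multilevel community detection on the weighted graph.

    The seed fixes the vertex-visit order of the greedy optimization (the
    result is order-sensitive).  Returns (compound -> community id,
    weighted modularity); an empty graph yields an empty partition.
    """
    if graph.vcount() == 0:
        return {}, float("nan")
    ig.set_random_number_generator(random.Random(seed))
    try:
        weights = graph.es["weight"] if graph.ecount() else None
        clustering = graph.community_multilevel(weights=weights)
    finally:
        ig.set_random_number_generator(random)
    membership = {
        graph.vs[i]["name"]: int(c) for i, c in enumerate(clustering.membership)
    }
    return membership, float(clustering.modularity)


def weighted_modularity(graph: ig.Graph, membership: dict[str, int]) -> float:
    """Weighted modularity of an arbitrary partition of the graph."""
    mem = [membership[v["name"]] for v in graph.vs]
    weights = graph.es["weight"] if graph.ecount() else None
    return float(graph.modularity(mem, weights=weights))


def community_composition(
    graph: ig.Graph,
    membership: dict[str, int],
    targets_of: dict[str, set[str]],
    family_of: dict[str, str],
) -> pd.DataFrame:
    """Per-community class composition, Fisher enrichment and family counts.

    The Fisher 2x2 table is (community membership) x (compound class) against
    the rest of the graph, two-sided.  Family counts tally the distinct
    qualifying targets of the community's members by protein family; targets
    without an annotation count under "unclassified".
    """
    if set(membership) != set(graph.vs["name"]):
        raise DataError("membership must cover exactly the graph's compounds")
    classes = {v["name"]: v["compound_class"] for v in graph.vs}
    total_np = sum(1 for c in classes.values() if c == "NP")
    total_ct = len(classes) - total_np
    rows = []
    for cid in sorted(set(membership.values())):
        members = sorted(c for c, m in membership.items() if m == cid)
        n_np = sum(1 for c in members if classes[c] == "NP")
        n_ct = len(members) - n_np
        table = [[n_np, n_ct], [total_np - n_np, total_ct - n_ct]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        targets = set().union(*(targets_of.get(c, set()) for c in members)) if members else set()
        fam_counts: dict[str, int] = {}
        for t in sorted(targets):
            fam = family_of.get(t, "unclassified")
            fam_counts[fam] = fam_counts.get(fam, 0) + 1
        rows.append(
            {
                "community_id": cid,
                "n_np": n_np,
                "n_ct": n_ct,
                "odds_ratio": float(odds) if odds is not None else float("inf"),
                "p_value": float(p),
                "n_targets": len(targets),
                "family_counts": ";".join(
                    f"{f}={n}" for f, n in sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0]))
                ),
            }
        )
    return pd.DataFrame(rows)
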