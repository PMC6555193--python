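"""Pathway-crosstalk network over entity-level pathways.

Nodes are entity-level (non-hierarchical) pathways; an edge connects two
pathways sharing at least one gene, weighted by the shared-gene count.
Distances are hop counts on the unweighted graph (weights are stored for
reporting only).  The set-to-set mean shortest path between NP-covered and
CT-covered pathway sets estimates synergistic potential; neighbor synergy
candidates are edges joining an NP-only pathway to a driver-enriched pathway
already reached by cancer drugs.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError


def build_pathway_graph(pathway_sets: dict[str, set[str]] | list[tuple[str, set[str]]]) -> nx.Graph:
    """Shared-gene pathway graph; edge weight = |gene intersection|."""
    if not isinstance(pathway_sets, dict):
        ids = [p for p, _ in pathway_sets]
        if len(ids) != len(set(ids)):
            dup = sorted({p for p in ids if ids.count(p) > 1})
            raise DataError(f"duplicate pathway ids: {dup}")
        pathway_sets = dict(pathway_sets)
    g = nx.Graph()
    g.add_nodes_from(sorted(pathway_sets))
    for p1, p2 in combinations(sorted(pathway_sets), 2):
        shared = pathway_sets[p1] & pathway_sets[p2]
        if shared:
            g.add_edge(p1, p2, weight=len(shared))
    return g


def label_nodes(graph: nx.Graph, labels: dict[str, str], enriched: set[str]) -> None:
    """Attach coverage label and driver-enriched flag to each pathway node."""
    for v in graph.nodes():
        graph.nodes[v]["label"] = labels.get(v, "NEITHER")
        graph.nodes[v]["enriched"] = v in enriched


def set_distance(graph: nx.Graph, set_a: set[str], set_b: set[str]) -> dict:
    """Mean hop distance between two pathway sets.

    Averages over all deduplicated unordered pairs {a, b}, a != b, a in A,
    b in B, restricted to pairs in the same connected component; the count
    of excluded (disconnected) pairs is reported.  With no usable pair the
    mean is NaN and ``defined`` is False.
    """
    if not set_a or not set_b:
        raise DataError("set_distance: both sets must be non-empty")
    pairs = {frozenset((a, b)) for a in set_a for b in set_b if a != b}
    # one BFS per distinct source node, reused across pairs
    lengths: dict[str, dict[str, int]] = {}
    total = 0.0
    used = 0
    excluded = 0
    for pair in pairs:
        a, b = sorted(pair)
        if a not in graph or b not in graph:
            excluded += 1
            continue
        if a not in lengths:
            lengths[a] = nx.single_source_shortest_path_length(graph, a)
        d = lengths[a].get(b)
        if d is None:
            excluded += 1
        else:
            total += d
            used += 1
    mean = total / used if used else float("nan")
    return {
        "mean_distance": mean,
        "n_pairs": used,
        "n_excluded": excluded,
        "defined": used > 0,
    }


def control_distance(
    graph: nx.Graph,
    size_a: int,
    size_b: int,
    n_reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of set_distance for random pathway sets."""
    nodes = sorted(graph.nodes())
    if size_a > len(nodes) or size_b > len(nodes) or size_a < 1 or size_b < 1:
        raise DataError("control_distance: infeasible set sizes")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        a = {nodes[i] for i in rng.choice(len(nodes), size=size_a, replace=False)}
        b = {nodes[i] for i in rng.choice(len(nodes), size=size_b, replace=False)}
        out[r] = set_distance(graph, a, b)["mean_distance"]
    return out


def empirical_p(observed: float, controls: np.ndarray) -> float:
    """(1 + #{controls <= observed}) / (n + 1), NaN controls dropped."""
    c = controls[~np.isnan(controls)]
    return (1 + int(np.sum(c <= observed))) / (len(c) + 1)


def neighbor_synergy_candidates(
    graph: nx.Graph,
    pathway_sets: dict[str, set[str]],
    np_targets: set[str] | None = None,
    ct_targets: set[str] | None = None,
) -> pd.DataFrame:
    """Edges pairing an NP-only pathway with a drug-reached enriched pathway.

    A candidate is an edge (P, Q) where P is labeled NP_ONLY and Q is
    driver-enriched with label CT_ONLY or BOTH (labels/flags must already be
    attached with :func:`label_nodes`).  Each candidate reports the shared
    genes and, when hit sets are supplied, the NP targets in P and CT
    targets in Q.
    """
    np_targets = np_targets or set()
    ct_targets = ct_targets or set()
    rows = []
    for u, v in graph.edges():
        for p, q in ((u, v), (v, u)):
            if graph.nodes[p]["label"] != "NP_ONLY":
                continue
            if not graph.nodes[q]["enriched"]:
                continue
            if graph.nodes[q]["label"] not in ("CT_ONLY", "BOTH"):
                continue
            shared = pathway_sets[p] & pathway_sets[q]
            rows.append(
                {
                    "np_pathway": p,
                    "enriched_pathway": q,
                    "enriched_label": graph.nodes[q]["label"],
                    "n_shared_genes": len(shared),
                    "shared_genes": "|".join(sorted(shared)),
                    "np_targets_in_np_pathway": "|".join(sorted(pathway_sets[p] & np_targets)),
                    "ct_targets_in_enriched_pathway": "|".join(sorted(pathway_sets[q] & ct_targets)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "np_pathway",
            "enriched_pathway",
            "enriched_label",
            "n_shared_genes",
            "shared_genes",
            "np_targets_in_np_pathway",
            "ct_targets_in_enriched_pathway",
        ],
    )
    return df.sort_values(["np_pathway", "enriched_pathway"]).reset_index(drop=True)
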