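"""PPI network topology of targeted vs untargeted nodes.

Targets are projected onto a protein-protein interaction network and each
node is profiled: degree, exact (Brandes) betweenness with each unordered
source-target pair counted once, eigenvector centrality (power iteration,
max-normalized so the top node scores 1), and mean shortest-path distance to
cancer driver nodes.  Node groups (NP_ONLY / CT_ONLY / BOTH / UNTARGETED)
are compared with two-sided Mann-Whitney U tests, and distance-to-driver
group means against size-matched random node sets.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)

GROUPS = ("NP_ONLY", "CT_ONLY", "BOTH", "UNTARGETED")
MEASURES = ("degree", "betweenness", "eigenvector", "mean_dist_to_drivers")


def load_network(path) -> nx.Graph:
    """Load an undirected simple graph from a TSV edge list or SIF file.

    TSV: header row, first two columns are the endpoints.  SIF: no header,
    ``node relation node`` whitespace-separated.  Self-loops and duplicate
    edges are dropped (counts logged); malformed rows raise with their line
    number.
    """
    path = str(path)
    is_sif = path.lower().endswith(".sif")
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        warnings.warn(f"{path}: empty network file", stacklevel=2)
        return g
    start = 0 if is_sif else 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if is_sif:
            if len(parts) < 3:
                raise DataError(f"{path}:{ln}: SIF row needs 3 fields")
            a, b = parts[0], parts[2]
        else:
            if len(parts) < 2:
                raise DataError(f"{path}:{ln}: edge row needs 2 fields")
            a, b = parts[0], parts[1]
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_self or n_dup:
        log.info("%s: dropped %d self-loops, %d duplicate edges", path, n_self, n_dup)
    return g


def eigenvector_scores(graph: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> dict[str, float]:
    """Principal-eigenvector centrality by power iteration, max-normalized.

    On disconnected graphs the iteration runs on the full adjacency; scores
    outside the dominant component decay toward zero.  Non-convergence
    raises, naming a node of the offending graph's largest component.
    """
    nodes = sorted(graph.nodes(), key=str)
    n = len(nodes)
    if n == 0:
        return {}
    if graph.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, dtype=float, format="csr")
    x = np.full(n, 1.0 / np.sqrt(n))
    # iterate on A + I: same principal eigenvector, but strictly dominant
    # eigenvalue even on bipartite graphs (whose +/- lambda pair would
    # otherwise make the plain iteration oscillate)
    for _ in range(max_iter):
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            mx = x.max()
            return {v: float(s / mx) for v, s in zip(nodes, x)}
        x = y
    comp = max(nx.connected_components(graph), key=len)
    raise DataError(
        f"eigenvector power iteration did not converge within {max_iter} "
        f"iterations (component containing {sorted(comp)[0]!r})"
    )


def distances_to_drivers(graph: nx.Graph, driver_set: set[str]) -> dict[str, float]:
    """Per-node mean shortest-path distance to reachable drivers.

    A driver's own distance excludes itself.  Nodes with no reachable driver
    get NaN (excluded from group means downstream).
    """
    if not driver_set:
        raise DataError("distances_to_drivers: empty driver set")
    drivers = [d for d in driver_set if d in graph]
    sums = {v: 0.0 for v in graph.nodes()}
    counts = {v: 0 for v in graph.nodes()}
    for d in drivers:
        for v, dist in nx.single_source_shortest_path_length(graph, d).items():
            if v == d:
                continue
            sums[v] += dist
            counts[v] += 1
    return {
        v: (sums[v] / counts[v]) if counts[v] else float("nan") for v in graph.nodes()
    }


def compute_profiles(
    graph: nx.Graph,
    np_targets: set[str],
    ct_targets: set[str],
    driver_set: set[str],
) -> pd.DataFrame:
    """Topology profile per node: centralities, driver distance, group label."""
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    eig = eigenvector_scores(graph)
    dist = distances_to_drivers(graph, driver_set) if driver_set else {}
    rows = []
    for v in sorted(graph.nodes(), key=str):
        in_np, in_ct = v in np_targets, v in ct_targets
        group = (
            "BOTH" if (in_np and in_ct)
            else "NP_ONLY" if in_np
            else "CT_ONLY" if in_ct
            else "UNTARGETED"
        )
        rows.append(
            {
                "node_id": v,
                "degree": graph.degree(v),
                "betweenness": betweenness[v],
                "eigenvector": eig.get(v, 0.0),
                "mean_dist_to_drivers": dist.get(v, float("nan")),
                "group": group,
                "is_driver": v in driver_set,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    profiles: pd.DataFrame,
    measure: str,
    groups: tuple[str, ...] = GROUPS,
    n_controls: int = 1000,
    seed: int = 0,
    min_group_size: int = 3,
) -> dict:
    """Pairwise Mann-Whitney tests plus random-control baselines.

    Returns {"pairwise": DataFrame, "controls": DataFrame or None, "seed"}.
    For ``mean_dist_to_drivers`` each group's mean is additionally compared
    with ``n_controls`` uniform random node sets of matched size; the
    empirical p is (1 + #{controls <= observed}) / (n_controls + 1).
    """
    if measure not in MEASURES:
        raise DataError(f"unknown measure {measure!r}")
    vals = {
        g: profiles.loc[profiles["group"] == g, measure].dropna().to_numpy()
        for g in groups
    }
    usable = []
    for g in groups:
        if len(vals[g]) < min_group_size:
            warnings.warn(
                f"group {g} has fewer than {min_group_size} members; skipped",
                stacklevel=2,
            )
        else:
            usable.append(g)
    rows = []
    for i, g1 in enumerate(usable):
        for g2 in usable[i + 1:]:
            u, p = stats.mannwhitneyu(vals[g1], vals[g2], alternative="two-sided")
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "n1": len(vals[g1]),
                    "n2": len(vals[g2]),
                    "U": float(u),
                    "p_value": float(p),
                }
            )
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "U", "p_value"])

    controls = None
    if measure == "mean_dist_to_drivers":
        rng = np.random.default_rng(seed)
        pool = profiles[measure].to_numpy()
        crows = []
        for g in usable:
            if g == "UNTARGETED":
                continue
            size = len(vals[g])
            obs = float(np.mean(vals[g]))
            n_le = 0
            for _ in range(n_controls):
                idx = rng.choice(len(pool), size=size, replace=False)
                sample = pool[idx]
                sample = sample[~np.isnan(sample)]
                if sample.size and float(np.mean(sample)) <= obs:
                    n_le += 1
            crows.append(
                {
                    "group": g,
                    "observed_mean": obs,
                    "n_controls": n_controls,
                    "empirical_p": (1 + n_le) / (n_controls + 1),
                }
            )
        controls = pd.DataFrame(crows)
    return {"pairwise": pairwise, "controls": controls, "seed": seed, "test": "mannwhitneyu_two_sided"}


def top_nodes_report(profiles: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k nodes per (group, measure); ties broken by node id.

    Mirrors a "top genes per topology measure" table: for each coverage
    group and each of degree / betweenness / eigenvector, the k highest
    scoring nodes with their value and driver flag.
    """
    rows = []
    for group in GROUPS:
        sub = profiles[profiles["group"] == group]
        for measure in ("degree", "betweenness", "eigenvector"):
            ranked = sub.sort_values(
                [measure, "node_id"], ascending=[False, True]
            ).head(k)
            for rank, (_, r) in enumerate(ranked.iterrows(), start=1):
                rows.append(
                    {
                        "group": group,
                        "measure": measure,
                        "rank": rank,
                        "node_id": r["node_id"],
                        "value": float(r[measure]),
                        "is_driver": bool(r["is_driver"]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["group", "measure", "rank", "node_id", "value", "is_driver"]
    )
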