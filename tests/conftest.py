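"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive quantities by exhaustive
enumeration (paths, subsets, ECDFs) so they stay independent of the library
code paths they are used to check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest

from npnet import evidence, pipeline, synthetic


# ---------------------------------------------------------------- oracles


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via the counting formula."""
    total = comb(N, n)
    s = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return Fraction(s, total)


def hypergeom_tail_enumeration(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by literally enumerating all C(N, n) draws (tiny N only)."""
    hits = 0
    total = 0
    successes = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by enumerating all shortest paths per pair."""
    out = {v: 0.0 for v in graph.nodes()}
    nodes = sorted(graph.nodes())
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def eigenvector_oracle(graph: nx.Graph) -> dict:
    """Max-normalized principal eigenvector from a dense eigendecomposition."""
    nodes = sorted(graph.nodes())
    a = nx.to_numpy_array(graph, nodelist=nodes)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    return {n: float(x / v.max()) for n, x in zip(nodes, v)}


def ks_statistic_oracle(a, b) -> float:
    """Two-sample KS D by a double loop over the pooled ECDF evaluation points."""
    a, b = list(a), list(b)
    d = 0.0
    for x in a + b:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 7) -> nx.Graph:
    """A random connected simple graph with 2..max_nodes nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    while True:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in combinations(range(n), 2):
            if rng.random() < 0.45:
                g.add_edge(i, j)
        if nx.is_connected(g):
            return g


# ---------------------------------------------------------------- fixtures


SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """Default-condition synthetic scenario: (dir, truth, config)."""
    d = tmp_path_factory.mktemp("scenario")
    cfg = synthetic.ScenarioConfig(seed=SCENARIO_SEED)
    truth = synthetic.generate_scenario(cfg, d)
    return d, truth, cfg


@pytest.fixture(scope="session")
def scenario_state(scenario, tmp_path_factory):
    """Pipeline state with catalog + aggregated interactions loaded."""
    d, truth, cfg = scenario
    out = tmp_path_factory.mktemp("stage_out")
    state = pipeline.PipelineState(
        config=pipeline.RunConfig(input_dir=str(d), output_dir=str(out), seed=SCENARIO_SEED)
    )
    pipeline.stage_integrate(state)
    pipeline.stage_evidence(state)
    pipeline._load_annotations(state)
    return state


def load_scenario_interactions(scenario_dir):
    """(interactions, classes) for a scenario without touching disk outputs."""
    import pandas as pd

    from npnet import catalog as cat

    df = pd.read_csv(scenario_dir / "compounds.tsv", sep="\t", dtype=str, keep_default_na=False)
    merged = cat.merge_compounds(cat.records_from_frame(df))
    idf = pd.read_csv(scenario_dir / "interactions.tsv", sep="\t", dtype=str, keep_default_na=False)
    items = evidence.evidence_from_frame(idf)
    import dataclasses

    kept = [
        dataclasses.replace(it, compound_id=merged.id_map[it.compound_id])
        for it in items
        if it.compound_id in merged.id_map
    ]
    return evidence.aggregate_all(kept), merged.classes()
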