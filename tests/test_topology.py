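"""PPI topology profiles against brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import betweenness_oracle, eigenvector_oracle, random_connected_graph
from npnet.errors import DataError
from npnet.topology import (
    compare_groups,
    compute_profiles,
    distances_to_drivers,
    eigenvector_scores,
    load_network,
    top_nodes_report,
)


def write_edges(path, rows, header=("protein_a", "protein_b")):
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def test_load_drops_duplicates_and_self_loops(tmp_path):
    f = tmp_path / "net.tsv"
    write_edges(f, [("A", "B"), ("B", "A"), ("A", "A")])
    g = load_network(f)
    assert g.number_of_nodes() == 2 and g.number_of_edges() == 1


def test_load_sif_format(tmp_path):
    f = tmp_path / "net.sif"
    f.write_text("A pp B\nB pp C\n")
    g = load_network(f)
    assert set(g.edges()) == {("A", "B"), ("B", "C")}


def test_load_malformed_row_reports_line(tmp_path):
    f = tmp_path / "net.tsv"
    f.write_text("protein_a\tprotein_b\nA\tB\nlonely\n")
    with pytest.raises(DataError, match=":3"):
        load_network(f)


def test_load_empty_file_warns(tmp_path):
    f = tmp_path / "net.tsv"
    f.write_text("")
    with pytest.warns(UserWarning, match="empty"):
        g = load_network(f)
    assert g.number_of_nodes() == 0


def profiles_for(graph, np_t=frozenset(), ct_t=frozenset(), drivers=frozenset({"zz"})):
    g = graph.copy()
    g.add_node("zz")  # dummy driver so distance profiles are defined
    return compute_profiles(g, set(np_t), set(ct_t), set(drivers))


def test_path_graph_betweenness():
    g = nx.path_graph(["A", "B", "C"])
    prof = profiles_for(g).set_index("node_id")
    assert prof.loc["B", "betweenness"] == 1.0
    assert prof.loc["A", "betweenness"] == 0.0


def test_star_graph_betweenness():
    g = nx.star_graph(3)  # center 0, three leaves
    prof = profiles_for(g).set_index("node_id")
    assert prof.loc[0, "betweenness"] == 3.0  # C(3,2) leaf pairs


def test_cycle_eigenvector_symmetry():
    g = nx.cycle_graph(5)
    scores = eigenvector_scores(g)
    assert all(s == pytest.approx(1.0) for s in scores.values())


def test_eigenvector_on_edgeless_graph_is_zero():
    g = nx.Graph()
    g.add_nodes_from("abc")
    assert set(eigenvector_scores(g).values()) == {0.0}


def test_centralities_match_brute_force_on_200_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        g = random_connected_graph(rng)
        prof = compute_profiles(g, set(), set(), {0}).set_index("node_id")
        bet = betweenness_oracle(g)
        eig = eigenvector_oracle(g)
        for v in g.nodes():
            assert prof.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert prof.loc[v, "eigenvector"] == pytest.approx(eig[v], abs=1e-6)
            assert prof.loc[v, "degree"] == g.degree(v)


def test_betweenness_conservation_identity():
    # sum of betweenness = sum over connected pairs of (d(s,t) - 1)
    rng = np.random.default_rng(5)
    for _ in range(20):
        g = random_connected_graph(rng)
        prof = profiles_for(g)
        total = prof[prof["node_id"] != "zz"]["betweenness"].sum()
        expected = sum(
            d - 1
            for s, lengths in dict(nx.all_pairs_shortest_path_length(g)).items()
            for t, d in lengths.items()
            if s < t
        )
        assert total == pytest.approx(expected)


def test_mean_distance_to_drivers_rules():
    g = nx.path_graph(["A", "B", "C"])
    d = distances_to_drivers(g, {"C"})
    assert d["A"] == 2.0
    # self excluded for driver nodes
    d2 = distances_to_drivers(g, {"B", "C"})
    assert d2["B"] == 1.0  # only distance to C counts
    # component without drivers -> undefined
    g.add_edge("X", "Y")
    d3 = distances_to_drivers(g, {"C"})
    assert math.isnan(d3["X"])


def test_compare_identical_groups_not_significant():
    g = nx.path_graph(range(12))
    prof = compute_profiles(g, set(range(0, 6)), set(range(6, 12)), {0})
    res = compare_groups(prof, "degree", groups=("NP_ONLY", "CT_ONLY"))
    assert res["pairwise"].iloc[0]["p_value"] > 0.5


def test_compare_separated_groups_significant():
    import pandas as pd

    rng = np.random.default_rng(0)
    rows = [
        {"node_id": f"a{i}", "degree": int(v), "group": "NP_ONLY", "is_driver": False}
        for i, v in enumerate(rng.integers(10, 21, 12))
    ] + [
        {"node_id": f"b{i}", "degree": int(v), "group": "UNTARGETED", "is_driver": False}
        for i, v in enumerate(rng.integers(100, 201, 12))
    ]
    prof = pd.DataFrame(rows)
    res = compare_groups(prof, "degree", groups=("NP_ONLY", "UNTARGETED"))
    assert res["pairwise"].iloc[0]["p_value"] < 0.05


def test_compare_groups_invariant_to_relabeling():
    g = nx.gnp_random_graph(20, 0.3, seed=2)
    prof = compute_profiles(g, {0, 1, 2, 3}, {4, 5, 6}, {7})
    relabeled = prof.copy()
    relabeled["node_id"] = ["n" + str(v) for v in relabeled["node_id"]]
    r1 = compare_groups(prof, "betweenness")
    r2 = compare_groups(relabeled, "betweenness")
    assert r1["pairwise"]["p_value"].tolist() == r2["pairwise"]["p_value"].tolist()


def test_undersized_group_skipped_with_warning():
    g = nx.path_graph(range(8))
    prof = compute_profiles(g, {0}, set(), {1})
    with pytest.warns(UserWarning, match="fewer than"):
        res = compare_groups(prof, "degree", groups=("NP_ONLY", "UNTARGETED"))
    assert res["pairwise"].empty


def test_distance_controls_empirical_p_range_and_seeding():
    g = nx.path_graph(range(30))
    prof = compute_profiles(g, set(range(5)), set(), {29})
    r1 = compare_groups(prof, "mean_dist_to_drivers", n_controls=50, seed=9)
    r2 = compare_groups(prof, "mean_dist_to_drivers", n_controls=50, seed=9)
    c1, c2 = r1["controls"], r2["controls"]
    assert c1["empirical_p"].tolist() == c2["empirical_p"].tolist()
    assert ((c1["empirical_p"] > 0) & (c1["empirical_p"] <= 1)).all()


def test_top_nodes_ranking_and_tie_break():
    g = nx.star_graph(4)
    prof = compute_profiles(g, {0}, set(), {1})
    top = top_nodes_report(prof, k=3)
    np_rows = top[(top["group"] == "NP_ONLY") & (top["measure"] == "degree")]
    assert np_rows.iloc[0]["node_id"] == 0
    # the four leaves tie on degree; lexicographically smaller id first
    un_rows = top[(top["group"] == "UNTARGETED") & (top["measure"] == "degree")]
    assert un_rows["node_id"].tolist() == sorted(un_rows["node_id"].tolist())


def test_driver_hubs_have_higher_degree_and_betweenness(scenario, scenario_state):
    """Planted extra driver edges make drivers topologically distinct."""
    d, truth, _ = scenario
    state = scenario_state
    graph = load_network(d / "ppi.tsv")
    prof = compute_profiles(graph, set(), set(), truth.planted_driver_set)
    from scipy import stats

    for measure in ("degree", "betweenness"):
        drv = prof.loc[prof["is_driver"], measure]
        non = prof.loc[~prof["is_driver"], measure]
        assert drv.median() > non.median()
        p = stats.mannwhitneyu(drv, non, alternative="two-sided").pvalue
        assert p < 0.05
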