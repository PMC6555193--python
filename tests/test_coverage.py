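"""Coverage classification, relative-increase arithmetic and KS comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ks_statistic_oracle
from npnet.coverage import (
    DEFAULT_STRATA,
    classify_entities,
    coverage_table,
    driver_tumor_coverage,
    hit_targets,
    ks_compare,
    per_compound_counts,
    per_compound_distributions,
    relative_increase,
    within_pathway_interaction_share,
)
from npnet.errors import DataError
from npnet.evidence import aggregate_all, select_stratum
from test_evidence import ev


def test_classification_rules():
    membership = {
        "p_np": {"A", "B"},
        "p_none": {"C", "D"},
        "p_both_no_shared": {"A", "E"},
    }
    labels = classify_entities({"A"}, {"E"}, membership)
    assert labels == {
        "p_np": "NP_ONLY",
        "p_none": "NEITHER",
        # BOTH does not require a single shared target
        "p_both_no_shared": "BOTH",
    }


def test_empty_membership_warns_and_is_neither():
    with pytest.warns(UserWarning, match="empty member set"):
        labels = classify_entities({"A"}, set(), {"p": set()})
    assert labels["p"] == "NEITHER"


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_labels_partition_the_universe(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(30)]
    membership = {
        f"p{j}": {genes[i] for i in rng.choice(30, size=rng.integers(1, 6), replace=False)}
        for j in range(12)
    }
    np_t = {g for g in genes if rng.random() < 0.2}
    ct_t = {g for g in genes if rng.random() < 0.2}
    labels = classify_entities(np_t, ct_t, membership)
    from collections import Counter

    counts = Counter(labels.values())
    assert sum(counts.values()) == len(membership)


def test_relative_increase_printed_values():
    assert round(relative_increase(725, 0, 1196)) == 61
    assert round(relative_increase(218, 266, 495)) == 29
    assert round(relative_increase(0, 5, 5)) == 0


def test_relative_increase_scale_invariant_and_undefined():
    assert relative_increase(10, 4, 6) == relative_increase(30, 12, 18)
    with pytest.raises(DataError):
        relative_increase(10, 0, 0)


def make_universe(n_np, n_ct, n_both, n_total):
    """Single-gene pathways with the requested coverage counts."""
    pathways = {}
    np_t, ct_t = set(), set()
    for i in range(n_total):
        g = f"g{i:05d}"
        pathways[f"p{i:05d}"] = {g}
        if i < n_np:
            np_t.add(g)
        elif i < n_np + n_ct:
            ct_t.add(g)
        elif i < n_np + n_ct + n_both:
            np_t.add(g)
            ct_t.add(g)
    return pathways, np_t, ct_t


@pytest.mark.parametrize(
    "n_np,n_ct,n_both,n_total,expected_pct_np",
    [
        (218, 266, 495, 1944, 11.21),  # full pathway universe
        (59, 0, 474, 533, 11.07),  # driver-enriched pathway universe
    ],
)
def test_pathway_percentages_match_printed_tables(n_np, n_ct, n_both, n_total, expected_pct_np):
    pathways, np_t, ct_t = make_universe(n_np, n_ct, n_both, n_total)
    items = [ev(cid="np1", tid=t, ref=True, value=50.0) for t in np_t]
    items += [ev(cid="ct1", tid=t, ref=True, value=50.0) for t in ct_t]
    inters = aggregate_all(items)
    classes = {"np1": "NP", "ct1": "CT"}
    table = coverage_table(inters, classes, pathways).set_index("stratum")
    row = table.loc["Evidence level III, binding LT100"]
    assert row["n_pathways_np_only"] == n_np
    assert row["pct_np_only"] == expected_pct_np


def test_within_pathway_share_hand_fixture():
    pathways = {"p1": {"a", "b"}, "p2": {"a", "c", "d"}, "p3": {"e"}}
    target_labels = {"a": "NP_ONLY", "b": "CT_ONLY", "c": "NP_ONLY", "d": "NEITHER", "e": "NP_ONLY"}
    pathway_labels = {"p1": "BOTH", "p2": "BOTH", "p3": "NP_ONLY"}
    # covered pairs in BOTH pathways: (p1,a) NP, (p1,b) CT, (p2,a) NP, (p2,c) NP
    share = within_pathway_interaction_share(pathway_labels, target_labels, pathways)
    assert share == pytest.approx(3 / 4)


def test_within_pathway_share_trivial_cases():
    pathways = {"p": {"a", "b"}}
    labels = {"p": "BOTH"}
    assert within_pathway_interaction_share(
        labels, {"a": "NP_ONLY", "b": "CT_ONLY"}, pathways
    ) == pytest.approx(0.5)
    assert within_pathway_interaction_share(
        labels, {"a": "NP_ONLY", "b": "NP_ONLY"}, pathways
    ) == pytest.approx(1.0)


def test_stratum_coverage_sets_are_nested(scenario_state):
    state = scenario_state
    covered_sets = []
    for _, levels, thr in reversed(DEFAULT_STRATA):
        sel = select_stratum(state.interactions, levels, thr)
        np_t, ct_t = hit_targets(sel, state.classes)
        labels = classify_entities(np_t, ct_t, state.pathways)
        covered_sets.append({p for p, l in labels.items() if l != "NEITHER"})
    for tighter, looser in zip(covered_sets, covered_sets[1:]):
        assert tighter <= looser


def test_driver_tumor_coverage_counts():
    driver_tt = {"D1": {"tt1", "tt2"}, "D2": {"tt1"}, "D3": {"tt2"}}
    items = [ev(cid="np1", tid="D1", ref=True, value=10.0)]
    inters = aggregate_all(items)
    df = driver_tumor_coverage(driver_tt, inters, {"np1": "NP"}, 100.0).set_index("tumor_type")
    assert df.loc["tt1", "np_only"] == 1 and df.loc["tt1", "total_drivers"] == 2
    assert df.loc["tt2", "np_only"] == 1 and df.loc["tt2", "both"] == 0
    assert bool(df.loc["tt1", "np_improved"]) and bool(df.loc["tt2", "np_improved"])


def test_driver_tumor_no_qualifying_interactions():
    driver_tt = {"D1": {"tt1"}}
    items = [ev(cid="np1", tid="D1", ref=True, value=5000.0)]
    df = driver_tumor_coverage(driver_tt, aggregate_all(items), {"np1": "NP"}, 100.0)
    row = df.iloc[0]
    assert row["np_only"] == 0 and row["ct_only"] == 0 and row["both"] == 0


def test_planted_np_only_driver_flags_its_tumor_types(scenario, scenario_state):
    _, truth, _ = scenario
    state = scenario_state
    df = driver_tumor_coverage(
        state.driver_tumor, state.interactions, state.classes, 100.0
    )
    sel = select_stratum(state.interactions, frozenset({"I", "II", "III"}), 100.0)
    np_t, ct_t = hit_targets(sel, state.classes)
    np_only_drivers = (np_t - ct_t) & truth.planted_driver_set
    flagged = set(df.loc[df["np_improved"], "tumor_type"])
    for d in np_only_drivers:
        assert state.driver_tumor[d] <= flagged


def test_ks_trivial_and_separated_samples():
    d, p = ks_compare([1, 2, 3], [1, 2, 3])
    assert d == 0.0 and p == pytest.approx(1.0)
    d, p = ks_compare([1, 2, 3], [4, 5, 6])
    assert d == 1.0


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.integers(0, 20), min_size=2, max_size=50),
    st.lists(st.integers(0, 20), min_size=2, max_size=50),
)
def test_ks_statistic_matches_double_loop_oracle(a, b):
    d, _ = ks_compare(a, b)
    assert d == pytest.approx(ks_statistic_oracle(a, b), abs=1e-12)


def test_per_compound_counts_pathways():
    pathways = {"p1": {"t1"}, "p2": {"t1", "t2"}, "p3": {"t2"}, "p4": {"x"}}
    items = [
        ev(cid="np1", tid="t1", ref=True, value=10.0),
        ev(cid="np1", tid="t2", ref=True, value=10.0),
    ]
    counts = per_compound_counts(
        aggregate_all(items), {"np1": "NP"}, pathways, {}, 100.0
    )
    assert counts["targets"]["NP"] == [2]
    assert counts["pathways"]["NP"] == [3]


def test_per_compound_distributions_skips_tiny_classes():
    items = [ev(cid="np1", tid="t1", ref=True, value=10.0)]
    with pytest.warns(UserWarning, match="skipped"):
        df = per_compound_distributions(
            aggregate_all(items), {"np1": "NP"}, {"p": {"t1"}}, {}, thresholds=(100.0,)
        )
    assert df.empty


def test_per_compound_distributions_on_scenario(scenario_state):
    state = scenario_state
    df = per_compound_distributions(
        state.interactions,
        state.classes,
        state.pathways,
        state.driver_tumor,
        thresholds=(100.0, 1000.0),
    )
    assert set(df["kind"]) == {"targets", "pathways", "tumor_types", "drivers"}
    assert ((df["ks_D"] >= 0) & (df["ks_D"] <= 1)).all()
    assert df["significant"].equals(df["p_value"] < 0.004)
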