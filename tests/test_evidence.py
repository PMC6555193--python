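"""Evidence grading, aggregation and affinity filtering."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from npnet.errors import DataError
from npnet.evidence import (
    Interaction,
    InteractionEvidence,
    aggregate_all,
    aggregate_interaction,
    assign_evidence_level,
    evidence_from_frame,
    filter_by_affinity,
    select_stratum,
    summarize_evidence,
    target_max_level,
)


def ev(cid="c1", tid="t1", src="db", ref=False, value=None, relation=None, assay=None):
    if value is not None and assay is None:
        assay = "IC50"
    if value is not None and relation is None:
        relation = "exact"
    return InteractionEvidence(
        compound_id=cid,
        target_id=tid,
        source_db=src,
        has_literature_ref=ref,
        assay_type=assay,
        relation=relation,
        value_nM=value,
    )


@pytest.mark.parametrize(
    "ref,value,expected",
    [
        (False, None, "I"),
        (True, None, "II"),
        (False, 50.0, "I"),  # value without accessible reference stays Level I
        (True, 50.0, "III"),
    ],
)
def test_level_truth_table(ref, value, expected):
    assert assign_evidence_level(ev(ref=ref, value=value)) == expected


def test_value_requires_assay_and_relation():
    with pytest.raises(DataError):
        InteractionEvidence("c", "t", "db", value_nM=5.0)


def test_aggregation_takes_max_level_and_min_exact_value():
    items = [
        ev(ref=False),  # I
        ev(ref=True, value=500.0),  # III
        ev(ref=True, value=80.0),  # III
        ev(ref=True, value=10.0, relation="gt"),  # qualified, ignored for best
    ]
    inter = aggregate_interaction(items)
    assert inter.max_level == "III"
    assert inter.best_exact_value_nM == 80.0


def test_single_level_one_item_is_identity():
    inter = aggregate_interaction([ev(ref=False)])
    assert inter.max_level == "I" and inter.best_exact_value_nM is None


def test_mixed_pairs_rejected():
    with pytest.raises(DataError, match="mixed pairs"):
        aggregate_interaction([ev(tid="t1"), ev(tid="t2")])


def test_only_relation_qualified_values_give_no_best_value():
    inter = aggregate_interaction([ev(ref=True, value=90.0, relation="lt")])
    assert inter.max_level == "III"
    assert inter.best_exact_value_nM is None


def test_target_max_level_overall_and_per_class():
    inters = aggregate_all(
        [
            ev(cid="np1", tid="T", ref=True),  # II
            ev(cid="np1", tid="T", ref=True, value=5.0),  # III -> pair III
            ev(cid="np2", tid="T", ref=False),  # I
            ev(cid="ct1", tid="T", ref=True, value=3.0),  # III
        ]
    )
    assert target_max_level("T", inters) == "III"
    per_class = target_max_level(
        "T", inters, classes={"np1": "NP", "np2": "NP", "ct1": "CT"}
    )
    assert per_class == {"NP": "III", "CT": "III"}
    only_np = aggregate_all([ev(cid="np2", tid="T", ref=False)])
    assert target_max_level("T", only_np, classes={"np2": "NP"}) == {"NP": "I"}
    with pytest.raises(DataError):
        target_max_level("missing", inters)


def test_affinity_filter_examples():
    kept = aggregate_all([ev(ref=True, value=50.0)])
    dropped = aggregate_all([ev(cid="c2", ref=True, value=150.0)])
    qualified = aggregate_all([ev(cid="c3", ref=True, value=90.0, relation="lt")])
    subset = filter_by_affinity(kept + dropped + qualified, 100.0)
    assert [i.compound_id for i in subset] == ["c1"]


@st.composite
def interaction_lists(draw):
    n = draw(st.integers(1, 15))
    out = []
    for i in range(n):
        value = draw(st.one_of(st.none(), st.floats(0.1, 1e6, allow_nan=False)))
        rel = draw(st.sampled_from(["exact", "lt", "gt"])) if value is not None else None
        out.append(
            ev(cid=f"c{i}", ref=draw(st.booleans()), value=value, relation=rel)
        )
    return aggregate_all(out)


@settings(max_examples=50, deadline=None)
@given(interaction_lists(), st.floats(1, 1e5), st.floats(1, 1e5))
def test_affinity_filter_monotone_in_threshold(inters, t1, t2):
    lo, hi = sorted((t1, t2))
    sub_lo = {(i.compound_id, i.target_id) for i in filter_by_affinity(inters, lo)}
    sub_hi = {(i.compound_id, i.target_id) for i in filter_by_affinity(inters, hi)}
    assert sub_lo <= sub_hi


@settings(max_examples=50, deadline=None)
@given(interaction_lists())
def test_max_level_monotone_under_added_evidence(inters):
    rank = {"I": 1, "II": 2, "III": 3}
    for inter in inters:
        for k in range(1, len(inter.evidence) + 1):
            sub = aggregate_interaction(inter.evidence[:k])
            assert rank[sub.max_level] <= rank[inter.max_level]


def test_summary_matches_hand_tally_on_mixed_fixture():
    # 20 hand-written evidence items over 8 pairs; tallied by hand below
    items = (
        [ev(cid="np1", tid="t1", ref=False) for _ in range(3)]  # pair I
        + [ev(cid="np1", tid="t2", ref=True)]  # pair II
        + [ev(cid="np2", tid="t1", ref=True, value=50.0), ev(cid="np2", tid="t1")]  # III
        + [ev(cid="np2", tid="t3", ref=True, value=20.0, relation="lt")]  # III, no exact
        + [ev(cid="np3", tid="t4", ref=False) for _ in range(2)]  # I
        + [ev(cid="ct1", tid="t1", ref=True, value=5.0) for _ in range(4)]  # III
        + [ev(cid="ct1", tid="t5", ref=True)]  # II
        + [ev(cid="ct2", tid="t2", ref=True, value=900.0) for _ in range(6)]  # III
    )
    assert len(items) == 20
    classes = {"np1": "NP", "np2": "NP", "np3": "NP", "ct1": "CT", "ct2": "CT"}
    inters = aggregate_all(items)
    tables = summarize_evidence(inters, classes)

    by_level = tables["interactions_by_level"].set_index(["class", "level"])["count"]
    # NP pairs: (np1,t1)=I, (np1,t2)=II, (np2,t1)=III, (np2,t3)=III, (np3,t4)=I
    assert by_level.loc[("NP", "I")] == 2
    assert by_level.loc[("NP", "II")] == 1
    assert by_level.loc[("NP", "III")] == 2
    # CT pairs: (ct1,t1)=III, (ct1,t5)=II, (ct2,t2)=III
    assert by_level.loc[("CT", "II")] == 1
    assert by_level.loc[("CT", "III")] == 2

    exact = tables["interactions_by_level_exact"].set_index(["class", "level"])["count"]
    # pairs with an exact value: (np2,t1), (ct1,t1), (ct2,t2)
    assert exact.loc[("NP", "III")] == 1
    assert exact.loc[("CT", "III")] == 2

    targets = tables["targets_by_max_level"].set_index(["class", "level"])["count"]
    # NP targets: t1 max(I, III)=III, t2=II, t3=III, t4=I
    assert targets.loc[("NP", "III")] == 2
    assert targets.loc[("NP", "II")] == 1
    assert targets.loc[("NP", "I")] == 1

    for name in ("interactions_by_level", "targets_by_max_level"):
        pct = tables[name].groupby("class")["pct"].sum()
        assert (abs(pct - 100.0) < 0.05).all()


def test_stratum_selection_levels_and_threshold():
    inters = aggregate_all(
        [
            ev(cid="a", ref=False),
            ev(cid="b", ref=True),
            ev(cid="c", ref=True, value=50.0),
            ev(cid="d", ref=True, value=500.0),
        ]
    )
    assert {i.compound_id for i in select_stratum(inters, {"II", "III"})} == {"b", "c", "d"}
    assert {i.compound_id for i in select_stratum(inters, {"III"}, 100.0)} == {"c"}


def test_loader_rejects_non_nM_units():
    df = pd.DataFrame(
        [
            {
                "compound_id": "c1",
                "target_id": "t1",
                "source_db": "db",
                "literature_ref_id": "REF1",
                "assay_type": "Ki",
                "relation": "exact",
                "value_nM": "2.0",
                "unit": "uM",
            }
        ]
    )
    with pytest.raises(DataError, match="unit"):
        evidence_from_frame(df)
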