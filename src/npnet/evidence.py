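"""Three-tier evidence framework for compound-target interactions.

Each database entry supporting a compound-target pair is one evidence item.
Items are graded:

* Level I   — database entry only (no accessible literature reference, no
  experimental binding value),
* Level II  — literature reference but no binding value,
* Level III — both a literature reference and an experimental binding value
  (IC50, EC50, Ki or KD, in nM).

A pair's interaction takes the maximum level over its items, and its binding
value is the minimum (most potent) over items reporting an *exact* value;
relation-qualified values ("<", ">") never qualify for threshold filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError

ASSAY_TYPES = ("IC50", "EC50", "Ki", "KD")
RELATIONS = ("exact", "lt", "gt")
LEVELS = ("I", "II", "III")
_LEVEL_RANK = {"I": 1, "II": 2, "III": 3}


@dataclass(frozen=True)
class InteractionEvidence:
    """A single database entry supporting one compound-target pair."""

    compound_id: str
    target_id: str
    source_db: str
    has_literature_ref: bool = False
    assay_type: str | None = None
    relation: str | None = None
    value_nM: float | None = None

    def __post_init__(self):
        if self.value_nM is not None:
            if self.assay_type is None or self.relation is None:
                raise DataError(
                    f"{self.compound_id}/{self.target_id}: a binding value "
                    "requires both assay_type and relation"
                )
            if self.value_nM <= 0:
                raise DataError(
                    f"{self.compound_id}/{self.target_id}: value_nM must be positive"
                )
        if self.assay_type is not None and self.assay_type not in ASSAY_TYPES:
            raise DataError(f"unknown assay_type {self.assay_type!r}")
        if self.relation is not None and self.relation not in RELATIONS:
            raise DataError(f"unknown relation {self.relation!r}")


@dataclass
class Interaction:
    """All evidence for one compound-target pair, aggregated."""

    compound_id: str
    target_id: str
    evidence: list[InteractionEvidence] = field(default_factory=list)
    max_level: str = "I"
    best_exact_value_nM: float | None = None


def assign_evidence_level(item: InteractionEvidence) -> str:
    """Grade one evidence item (pure function of ref and value presence)."""
    if item.value_nM is not None and item.has_literature_ref:
        return "III"
    if item.has_literature_ref:
        return "II"
    return "I"


def aggregate_interaction(items: list[InteractionEvidence]) -> Interaction:
    """Aggregate the evidence items of a single compound-target pair.

    max_level is the maximum item level; best_exact_value_nM is the minimum
    over items with relation="exact" (None if no exact value exists).
    """
    if not items:
        raise DataError("aggregate_interaction requires at least one evidence item")
    pair = (items[0].compound_id, items[0].target_id)
    for it in items:
        if (it.compound_id, it.target_id) != pair:
            raise DataError(
                f"mixed pairs in aggregation: {pair} vs "
                f"{(it.compound_id, it.target_id)}"
            )
    max_level = max((assign_evidence_level(it) for it in items), key=_LEVEL_RANK.get)
    exact = [it.value_nM for it in items if it.relation == "exact" and it.value_nM is not None]
    return Interaction(
        compound_id=pair[0],
        target_id=pair[1],
        evidence=list(items),
        max_level=max_level,
        best_exact_value_nM=min(exact) if exact else None,
    )


def aggregate_all(items: list[InteractionEvidence]) -> list[Interaction]:
    """Group evidence items by pair and aggregate each pair."""
    groups: dict[tuple[str, str], list[InteractionEvidence]] = {}
    for it in items:
        groups.setdefault((it.compound_id, it.target_id), []).append(it)
    return [aggregate_interaction(groups[k]) for k in sorted(groups)]


def target_max_level(
    target_id: str,
    interactions: list[Interaction],
    classes: dict[str, str] | None = None,
) -> str | dict[str, str]:
    """Maximum evidence level over all interactions touching a target.

    With ``classes`` (compound_id -> "NP"/"CT") the rule is applied per
    compound class and a dict {class: level} is returned (classes with no
    interaction on the target are absent).
    """
    touching = [i for i in interactions if i.target_id == target_id]
    if not touching:
        raise DataError(f"unknown target {target_id!r}: no interactions")
    if classes is None:
        return max((i.max_level for i in touching), key=_LEVEL_RANK.get)
    out: dict[str, str] = {}
    for i in touching:
        cls = classes[i.compound_id]
        cur = out.get(cls)
        if cur is None or _LEVEL_RANK[i.max_level] > _LEVEL_RANK[cur]:
            out[cls] = i.max_level
    return out


def filter_by_affinity(
    interactions: list[Interaction], threshold_nM: float
) -> list[Interaction]:
    """Keep interactions with an exact binding value strictly below threshold."""
    if threshold_nM <= 0:
        raise DataError("affinity threshold must be positive")
    return [
        i
        for i in interactions
        if i.best_exact_value_nM is not None and i.best_exact_value_nM < threshold_nM
    ]


def select_stratum(
    interactions: list[Interaction],
    levels: set[str] | frozenset[str],
    threshold_nM: float | None = None,
) -> list[Interaction]:
    """Interactions whose max level lies in ``levels``, optionally < threshold."""
    sel = [i for i in interactions if i.max_level in levels]
    if threshold_nM is not None:
        sel = filter_by_affinity(sel, threshold_nM)
    return sel


def _share_table(counts: pd.Series) -> pd.DataFrame:
    df = counts.rename("count").reset_index()
    totals = df.groupby("class")["count"].transform("sum")
    df["pct"] = (100.0 * df["count"] / totals).round(2)
    return df


def summarize_evidence(
    interactions: list[Interaction], classes: dict[str, str]
) -> dict[str, pd.DataFrame]:
    """Interaction and target count tables by compound class and level.

    Returns four tables: interaction counts by (class, level); the same
    restricted to interactions carrying an exact binding value; target counts
    by (class, per-class max level); the same restricted to exact-value
    interactions.  Each table carries a per-class percentage column.
    """

    def interaction_counts(inters: list[Interaction]) -> pd.DataFrame:
        rows = [
            {"class": classes[i.compound_id], "level": i.max_level} for i in inters
        ]
        df = pd.DataFrame(rows, columns=["class", "level"])
        counts = df.groupby(["class", "level"], sort=True).size()
        return _share_table(counts)

    def target_counts(inters: list[Interaction]) -> pd.DataFrame:
        best: dict[tuple[str, str], str] = {}
        for i in inters:
            key = (classes[i.compound_id], i.target_id)
            cur = best.get(key)
            if cur is None or _LEVEL_RANK[i.max_level] > _LEVEL_RANK[cur]:
                best[key] = i.max_level
        df = pd.DataFrame(
            [{"class": c, "level": lv} for (c, _), lv in best.items()],
            columns=["class", "level"],
        )
        counts = df.groupby(["class", "level"], sort=True).size()
        return _share_table(counts)

    exact = [i for i in interactions if i.best_exact_value_nM is not None]
    return {
        "interactions_by_level": interaction_counts(interactions),
        "interactions_by_level_exact": interaction_counts(exact),
        "targets_by_max_level": target_counts(interactions),
        "targets_by_max_level_exact": target_counts(exact),
    }


def evidence_from_frame(df: pd.DataFrame) -> list[InteractionEvidence]:
    """Parse an interactions table into evidence items.

    Expected columns: compound_id, target_id, source_db, literature_ref_id
    (empty allowed), assay_type, relation, value_nM, unit.  Rows carrying a
    binding value in any unit other than nM are rejected.
    """
    items = []
    for idx, row in df.iterrows():
        raw_val = str(row.get("value_nM", "")).strip()
        value = float(raw_val) if raw_val else None
        unit = str(row.get("unit", "")).strip()
        if value is not None and unit != "nM":
            raise DataError(f"interactions row {idx}: unit must be 'nM', got {unit!r}")
        assay = str(row.get("assay_type", "")).strip() or None
        rel = str(row.get("relation", "")).strip() or None
        items.append(
            InteractionEvidence(
                compound_id=str(row["compound_id"]),
                target_id=str(row["target_id"]),
                source_db=str(row["source_db"]),
                has_literature_ref=bool(str(row.get("literature_ref_id", "")).strip()),
                assay_type=assay,
                relation=rel,
                value_nM=value,
            )
        )
    return items
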