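"""Compound catalog: multi-key identity merging and drug scrubbing.

Compound records arrive from several source databases, each carrying some
subset of five identifying keys (chemical name, SMILES, InChIKey, PubChem
CID, CAS number).  Two records denote the same compound when they are
connected under the transitive closure of "share at least one exactly
matching key".  Names are compared case-insensitively after trimming and
collapsing internal whitespace; the other keys are compared verbatim.

Merging is performed within a compound class: natural products (NP) and
Cancer Targetome drugs (CT) are curated independently and a record's class
never changes.  After merging, the NP side can be scrubbed against exclusion
key sets (known non-NP drugs); CT compounds are never removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError

KEY_FIELDS = ("name", "smiles", "inchikey", "pubchem_cid", "cas")

_WS = re.compile(r"\s+")


def normalize_key(field_name: str, value: str | None) -> str | None:
    """Canonical form used for key comparison (None for null/blank)."""
    if value is None:
        return None
    value = str(value).strip()
    if not value:
        return None
    if field_name == "name":
        return _WS.sub(" ", value).lower()
    return value


@dataclass(frozen=True)
class CompoundKeySet:
    """Up to five identifying keys; at least one must be non-null."""

    name: str | None = None
    smiles: str | None = None
    inchikey: str | None = None
    pubchem_cid: str | None = None
    cas: str | None = None

    def normalized_items(self) -> list[tuple[str, str]]:
        out = []
        for f in KEY_FIELDS:
            v = normalize_key(f, getattr(self, f))
            if v is not None:
                out.append((f, v))
        return out

    def is_empty(self) -> bool:
        return not self.normalized_items()


@dataclass(frozen=True)
class CompoundRecord:
    """One source-level compound record prior to merging."""

    compound_id: str
    compound_class: str  # "NP" or "CT"
    keys: CompoundKeySet
    source_dbs: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.compound_class not in ("NP", "CT"):
            raise DataError(
                f"compound {self.compound_id!r}: class must be NP or CT, "
                f"got {self.compound_class!r}"
            )


@dataclass
class MergedCompound:
    """A unified compound: field-wise union of its member records' keys."""

    compound_id: str
    compound_class: str
    key_values: dict[str, tuple[str, ...]]  # field -> sorted original values
    source_dbs: frozenset[str]
    member_ids: tuple[str, ...]  # original record compound_ids


@dataclass
class Catalog:
    compounds: list[MergedCompound]
    id_map: dict[str, str] = field(default_factory=dict)  # record id -> merged id
    conflicts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["compound_id", "field", "values"])
    )

    def __len__(self) -> int:
        return len(self.compounds)

    def by_id(self) -> dict[str, MergedCompound]:
        return {c.compound_id: c for c in self.compounds}

    def classes(self) -> dict[str, str]:
        return {c.compound_id: c.compound_class for c in self.compounds}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.compounds:
            row = {"compound_id": c.compound_id, "class": c.compound_class}
            for f in KEY_FIELDS:
                row[f] = "|".join(c.key_values.get(f, ()))
            row["source_dbs"] = "|".join(sorted(c.source_dbs))
            rows.append(row)
        return pd.DataFrame(
            rows, columns=["compound_id", "class", *KEY_FIELDS, "source_dbs"]
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller root for deterministic grouping
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def merge_compounds(records: list[CompoundRecord]) -> Catalog:
    """Partition records into unique compounds via shared-key closure.

    Records belong to the same output compound iff they are connected under
    the transitive closure of sharing at least one exactly matching key
    (within the same compound class).  The merged compound keeps the
    field-wise union of its members' key values; a field with more than one
    distinct original value is flagged in the conflict report.

    Raises
    ------
    DataError
        If a record carries no usable key (reported with its list index).
    """
    for i, rec in enumerate(records):
        if rec.keys.is_empty():
            raise DataError(f"record {i} ({rec.compound_id!r}): all keys are null")

    uf = _UnionFind(len(records))
    seen: dict[tuple[str, str, str], int] = {}  # (class, field, value) -> record idx
    for i, rec in enumerate(records):
        for f, v in rec.keys.normalized_items():
            k = (rec.compound_class, f, v)
            if k in seen:
                uf.union(seen[k], i)
            else:
                seen[k] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(uf.find(i), []).append(i)

    compounds: list[MergedCompound] = []
    id_map: dict[str, str] = {}
    conflict_rows = []
    for root in sorted(groups):
        members = groups[root]
        recs = [records[i] for i in members]
        merged_id = min(r.compound_id for r in recs)
        key_values: dict[str, tuple[str, ...]] = {}
        for f in KEY_FIELDS:
            # distinct original (un-normalized within name case) values, keyed
            # on the normalized form so "Taxol" and "taxol" are one value
            by_norm: dict[str, str] = {}
            for r in recs:
                v = getattr(r.keys, f)
                nv = normalize_key(f, v)
                if nv is not None and nv not in by_norm:
                    by_norm[nv] = str(v).strip()
            if by_norm:
                key_values[f] = tuple(sorted(by_norm.values()))
                if len(by_norm) > 1:
                    conflict_rows.append(
                        {
                            "compound_id": merged_id,
                            "field": f,
                            "values": "|".join(sorted(by_norm.values())),
                        }
                    )
        merged = MergedCompound(
            compound_id=merged_id,
            compound_class=recs[0].compound_class,
            key_values=key_values,
            source_dbs=frozenset().union(*(r.source_dbs for r in recs)),
            member_ids=tuple(sorted(r.compound_id for r in recs)),
        )
        compounds.append(merged)
        for r in recs:
            id_map[r.compound_id] = merged_id

    compounds.sort(key=lambda c: c.compound_id)
    conflicts = pd.DataFrame(conflict_rows, columns=["compound_id", "field", "values"])
    return Catalog(compounds=compounds, id_map=id_map, conflicts=conflicts)


def scrub_drugs(
    catalog: Catalog, exclusion_keysets: list[CompoundKeySet]
) -> tuple[Catalog, pd.DataFrame]:
    """Remove NP compounds matching an exclusion key set on any key.

    Matching uses the same normalization as merging.  CT compounds are never
    removed.  Returns the reduced catalog and a report of removed compounds
    with the matching key field and value.
    """
    excl: dict[tuple[str, str], str] = {}
    for ks in exclusion_keysets:
        for f, v in ks.normalized_items():
            excl.setdefault((f, v), v)

    kept: list[MergedCompound] = []
    removed_rows = []
    for c in catalog.compounds:
        hit = None
        if c.compound_class == "NP":
            for f, values in c.key_values.items():
                for v in values:
                    nv = normalize_key(f, v)
                    if nv is not None and (f, nv) in excl:
                        hit = (f, v)
                        break
                if hit:
                    break
        if hit:
            removed_rows.append(
                {"compound_id": c.compound_id, "matched_field": hit[0], "matched_value": hit[1]}
            )
        else:
            kept.append(c)

    removed_ids = {r["compound_id"] for r in removed_rows}
    id_map = {k: v for k, v in catalog.id_map.items() if v not in removed_ids}
    removed = pd.DataFrame(
        removed_rows, columns=["compound_id", "matched_field", "matched_value"]
    )
    return Catalog(compounds=kept, id_map=id_map, conflicts=catalog.conflicts), removed


def records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    """Build records from a compounds table (one row per source record)."""
    records = []
    for _, row in df.iterrows():
        keys = CompoundKeySet(
            **{f: (row[f] if str(row.get(f, "")).strip() else None) for f in KEY_FIELDS}
        )
        srcs = str(row.get("source_dbs", "")).strip()
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                compound_class=str(row["class"]),
                keys=keys,
                source_dbs=frozenset(s for s in srcs.split("|") if s),
            )
        )
    return records


def exclusion_keysets_from_frame(df: pd.DataFrame) -> list[CompoundKeySet]:
    out = []
    for _, row in df.iterrows():
        out.append(
            CompoundKeySet(
                **{f: (row[f] if str(row.get(f, "")).strip() else None) for f in KEY_FIELDS}
            )
        )
    return out
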