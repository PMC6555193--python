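"""Seeded synthetic input scenarios emulating the source databases.

The real analysis integrates seven public compound-target databases, a
pathway knowledgebase with a hierarchy, a driver-gene catalog with tumor
types, protein-family annotations and PPI networks.  None of those inputs
ships with the package, so this module generates complete, statistically
structured stand-ins:

* multi-source evidence multiplicity per compound-target pair, with
  configurable literature-reference and binding-value probabilities and a
  log-normal spread of binding affinities (nM) including relation-qualified
  ("<", ">") entries,
* family-structured target sharing (compounds preferentially sample targets
  from their own protein family),
* planted driver-enriched pathways (members drawn predominantly from the
  driver set) of which a subset are planted NP-only opportunity pathways
  (at least one NP interaction with an exact value < 100 nM and no CT
  interaction below 100 nM),
* a PPI network with denser within-pathway wiring and extra random edges on
  driver nodes, so the topology contrast between drivers and non-drivers is
  recoverable,
* a pathway hierarchy (random forest) whose leaves are flagged entity-level,
* duplicate compound records across sources (exercising key-based merging)
  and an exclusion list naming a few NP compounds (exercising scrubbing).

The ground truth of everything planted is returned as a
:class:`ScenarioTruth` and written as JSON, so recovery tests can score the
pipeline against it.  Identical config + seed reproduce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

SOURCE_PREFIX = "DB"


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic scenario (defaults are the study conditions)."""

    seed: int = 0
    n_np_compounds: int = 150
    n_ct_compounds: int = 50
    n_targets: int = 500
    n_families: int = 20
    n_pathways: int = 60
    entity_level_fraction: float = 0.5
    pathway_size_range: tuple[int, int] = (10, 40)
    driver_fraction: float = 0.15
    n_tumor_types: int = 20
    n_sources: int = 7
    p_literature_ref: float = 0.5
    p_binding_value: float = 0.4
    affinity_log10_nM_mean: float = 2.0
    affinity_log10_nM_sd: float = 1.5
    mean_targets_per_compound: float = 5.0
    family_affinity_bias: float = 8.0
    n_planted_enriched_pathways: int = 8
    n_planted_opportunity_pathways: int = 3
    ppi_within_pathway_edge_p: float = 0.08
    ppi_background_edge_p: float = 0.004
    driver_extra_degree: int = 10
    # secondary knobs
    planted_driver_member_fraction: float = 0.7  # >= 0.6 by construction
    relation_qualifier_fraction: float = 0.15
    ct_value_implies_ref: bool = True
    p_extra_source_record: float = 0.4  # chance a compound gets a 2nd catalog row
    n_excluded_np: int = 5

    def validate(self) -> None:
        probs = {
            "entity_level_fraction": self.entity_level_fraction,
            "driver_fraction": self.driver_fraction,
            "p_literature_ref": self.p_literature_ref,
            "p_binding_value": self.p_binding_value,
            "ppi_within_pathway_edge_p": self.ppi_within_pathway_edge_p,
            "ppi_background_edge_p": self.ppi_background_edge_p,
            "relation_qualifier_fraction": self.relation_qualifier_fraction,
            "p_extra_source_record": self.p_extra_source_record,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        counts = {
            "n_np_compounds": self.n_np_compounds,
            "n_ct_compounds": self.n_ct_compounds,
            "n_targets": self.n_targets,
            "n_families": self.n_families,
            "n_pathways": self.n_pathways,
            "n_tumor_types": self.n_tumor_types,
            "n_sources": self.n_sources,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"pathway_size_range invalid: {self.pathway_size_range}")
        if hi > self.n_targets:
            raise ConfigError("pathway_size_range.max exceeds n_targets")
        if self.mean_targets_per_compound <= 0:
            raise ConfigError("mean_targets_per_compound must be positive")
        if self.family_affinity_bias <= 0:
            raise ConfigError("family_affinity_bias must be positive")
        if self.n_planted_enriched_pathways > self.n_pathways:
            raise ConfigError("more planted enriched pathways than pathways")
        if self.n_planted_enriched_pathways >= self.n_pathways:
            raise ConfigError("at least one non-planted pathway is required")
        if self.n_planted_opportunity_pathways > self.n_planted_enriched_pathways:
            raise ConfigError("opportunity pathways must be a subset of enriched ones")
        if self.n_planted_enriched_pathways and math.floor(
            self.driver_fraction * self.n_targets
        ) < math.ceil(self.planted_driver_member_fraction * lo):
            raise ConfigError("driver set too small to populate planted pathways")
        if not (0.6 <= self.planted_driver_member_fraction <= 1.0):
            raise ConfigError("planted_driver_member_fraction must lie in [0.6, 1]")
        if self.driver_extra_degree < 0:
            raise ConfigError("driver_extra_degree must be non-negative")
        if self.n_excluded_np > self.n_np_compounds:
            raise ConfigError("cannot exclude more NP compounds than exist")


@dataclass
class ScenarioTruth:
    """Ground truth of everything the generator planted."""

    planted_enriched_pathway_ids: set[str] = field(default_factory=set)
    planted_opportunity_pathway_ids: set[str] = field(default_factory=set)
    planted_family_of_compound: dict[str, str] = field(default_factory=dict)
    planted_driver_set: set[str] = field(default_factory=set)
    planted_excluded_np_ids: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_enriched_pathway_ids": sorted(self.planted_enriched_pathway_ids),
                "planted_opportunity_pathway_ids": sorted(self.planted_opportunity_pathway_ids),
                "planted_family_of_compound": dict(sorted(self.planted_family_of_compound.items())),
                "planted_driver_set": sorted(self.planted_driver_set),
                "planted_excluded_np_ids": sorted(self.planted_excluded_np_ids),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioTruth":
        d = json.loads(text)
        return cls(
            planted_enriched_pathway_ids=set(d["planted_enriched_pathway_ids"]),
            planted_opportunity_pathway_ids=set(d["planted_opportunity_pathway_ids"]),
            planted_family_of_compound=dict(d["planted_family_of_compound"]),
            planted_driver_set=set(d["planted_driver_set"]),
            planted_excluded_np_ids=set(d.get("planted_excluded_np_ids", [])),
        )


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: list[str], weights: np.ndarray, k: int
) -> list[str]:
    """Gumbel top-k trick: weighted sampling without replacement."""
    k = min(k, len(items))
    keys = np.log(weights) + rng.gumbel(size=len(items))
    idx = np.argpartition(-keys, k - 1)[:k]
    return [items[i] for i in sorted(idx)]


def generate_evidence_mixture(
    pairs: list[tuple[str, str]],
    config: ScenarioConfig,
    rng: np.random.Generator,
    classes: dict[str, str],
    forced_lt100: set[tuple[str, str]] = frozenset(),
) -> list[dict]:
    """Evidence items for each compound-target pair.

    Each pair receives 1..n_sources items from distinct sources.  An item
    carries a literature reference with ``p_literature_ref`` and a binding
    value with ``p_binding_value`` (for CT compounds a value forces a
    reference when ``ct_value_implies_ref``); values are log-normal in nM
    and a configurable fraction carries a "<" or ">" qualifier instead of an
    exact value.  Pairs in ``forced_lt100`` get one guaranteed item with a
    reference and an exact value below 100 nM.
    """
    sources = [f"{SOURCE_PREFIX}{i + 1:02d}" for i in range(config.n_sources)]
    rows: list[dict] = []
    for compound_id, target_id in pairs:
        n_items = 1 + int(rng.binomial(config.n_sources - 1, 0.2))
        item_sources = [
            sources[i] for i in sorted(rng.choice(config.n_sources, size=n_items, replace=False))
        ]
        forced = (compound_id, target_id) in forced_lt100
        for j, src in enumerate(item_sources):
            has_ref = bool(rng.random() < config.p_literature_ref)
            has_value = bool(rng.random() < config.p_binding_value)
            if forced and j == 0:
                has_ref = has_value = True
            if (
                has_value
                and config.ct_value_implies_ref
                and classes[compound_id] == "CT"
            ):
                has_ref = True
            assay = relation = ""
            value = ""
            if has_value:
                assay = ("IC50", "EC50", "Ki", "KD")[int(rng.integers(4))]
                if forced and j == 0:
                    relation = "exact"
                    v = float(10 ** rng.uniform(0.0, 1.9))  # 1..~80 nM
                else:
                    u = rng.random()
                    if u < config.relation_qualifier_fraction:
                        relation = "lt" if rng.random() < 0.5 else "gt"
                    else:
                        relation = "exact"
                    v = float(
                        10 ** rng.normal(config.affinity_log10_nM_mean, config.affinity_log10_nM_sd)
                    )
                value = f"{v:.6g}"
            ref = f"REF{int(rng.integers(1, 10 ** 6)):06d}" if has_ref else ""
            rows.append(
                {
                    "compound_id": compound_id,
                    "target_id": target_id,
                    "source_db": src,
                    "literature_ref_id": ref,
                    "assay_type": assay,
                    "relation": relation,
                    "value_nM": value,
                    "unit": "nM" if has_value else "",
                }
            )
    return rows


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def generate_scenario(config: ScenarioConfig, outdir) -> ScenarioTruth:
    """Write a complete input scenario to ``outdir`` and return its truth.

    Files written: compounds.tsv, interactions.tsv, pathways.gmt,
    pathway_hierarchy.tsv, ppi.tsv, drivers.tsv, families.tsv,
    exclusion_list.tsv, truth.json, run_manifest.json.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    targets = [f"G{i:04d}" for i in range(1, config.n_targets + 1)]
    families = [f"FAM{i:02d}" for i in range(1, config.n_families + 1)]
    target_family = {
        t: families[int(i)] for t, i in zip(targets, rng.integers(0, config.n_families, len(targets)))
    }

    n_drivers = math.floor(config.driver_fraction * config.n_targets)
    driver_set = set(
        targets[i] for i in sorted(rng.choice(config.n_targets, size=n_drivers, replace=False))
    )
    drivers = sorted(driver_set)
    non_drivers = [t for t in targets if t not in driver_set]

    # ---- pathways: planted driver-enriched first, then background ----
    lo, hi = config.pathway_size_range
    pathway_ids = [f"PW{i:04d}" for i in range(1, config.n_pathways + 1)]
    planted = pathway_ids[: config.n_planted_enriched_pathways]
    opportunity = planted[: config.n_planted_opportunity_pathways]
    pathway_sets: dict[str, set[str]] = {}
    for pid in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        if pid in planted:
            n_drv = min(math.ceil(config.planted_driver_member_fraction * size), len(drivers))
            members = set(
                drivers[i] for i in rng.choice(len(drivers), size=n_drv, replace=False)
            )
            pool = non_drivers
            extra = size - len(members)
            if extra > 0:
                members |= {pool[i] for i in rng.choice(len(pool), size=extra, replace=False)}
        else:
            members = {targets[i] for i in rng.choice(config.n_targets, size=size, replace=False)}
        pathway_sets[pid] = members
    # closed world: every target sits in at least one (non-planted) pathway
    covered = set().union(*pathway_sets.values())
    background = [p for p in pathway_ids if p not in planted]
    for t in targets:
        if t not in covered:
            pid = background[int(rng.integers(len(background)))]
            pathway_sets[pid].add(t)

    # ---- hierarchy: a random forest; entity-level = leaves ----
    n_entity = max(1, math.floor(config.entity_level_fraction * config.n_pathways))
    n_entity = max(n_entity, len(planted))  # planted pathways stay entity-level leaves
    entity_ids = set(planted)
    for pid in background:
        if len(entity_ids) >= n_entity:
            break
        entity_ids.add(pid)
    internal = [p for p in pathway_ids if p not in entity_ids]
    parent_of: dict[str, str] = {}
    for i, pid in enumerate(internal):
        if i == 0 or rng.random() < 0.25:
            continue  # a root
        parent_of[pid] = internal[int(rng.integers(i))]
    for pid in sorted(entity_ids):
        if internal:
            parent_of[pid] = internal[int(rng.integers(len(internal)))]
    hierarchy = pd.DataFrame(
        {
            "pathway_id": pathway_ids,
            "parent_id": [parent_of.get(p, "") for p in pathway_ids],
            "entity_level": [int(p in entity_ids) for p in pathway_ids],
        }
    )

    # ---- PPI: dense within pathways, sparse background, hub drivers ----
    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    for pid in pathway_ids:
        members = sorted(pathway_sets[pid])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < config.ppi_within_pathway_edge_p:
                    add_edge(members[i], members[j])
    n_possible = config.n_targets * (config.n_targets - 1) // 2
    n_bg = int(rng.binomial(n_possible, config.ppi_background_edge_p))
    for _ in range(n_bg):
        i, j = rng.integers(config.n_targets), rng.integers(config.n_targets)
        add_edge(targets[int(i)], targets[int(j)])
    for d in drivers:
        for _ in range(config.driver_extra_degree):
            add_edge(d, targets[int(rng.integers(config.n_targets))])
    # no isolated targets (closed world for downstream joins)
    touched = {v for e in edges for v in e}
    for t in targets:
        if t not in touched:
            other = targets[int(rng.integers(config.n_targets))]
            while other == t:
                other = targets[int(rng.integers(config.n_targets))]
            add_edge(t, other)

    # ---- compounds, families, targets-per-compound ----
    np_ids = [f"NP{i:04d}" for i in range(1, config.n_np_compounds + 1)]
    ct_ids = [f"CT{i:04d}" for i in range(1, config.n_ct_compounds + 1)]
    compound_ids = np_ids + ct_ids
    classes = {c: ("NP" if c.startswith("NP") else "CT") for c in compound_ids}
    compound_family = {
        c: families[int(i)]
        for c, i in zip(compound_ids, rng.integers(0, config.n_families, len(compound_ids)))
    }
    targets_by_family: dict[str, np.ndarray] = {
        fam: np.array([t == fam for t in (target_family[g] for g in targets)])
        for fam in families
    }
    pair_set: set[tuple[str, str]] = set()
    for c in compound_ids:
        k = max(1, int(rng.poisson(config.mean_targets_per_compound)))
        weights = np.where(targets_by_family[compound_family[c]], config.family_affinity_bias, 1.0)
        for t in _weighted_sample_without_replacement(rng, targets, weights, k):
            pair_set.add((c, t))

    # ---- opportunity planting: NP hit < 100 nM, CT kept >= 100 nM ----
    forced_lt100: set[tuple[str, str]] = set()
    opp_members: set[str] = set()
    for idx, pid in enumerate(opportunity):
        opp_members |= pathway_sets[pid]
        members = sorted(pathway_sets[pid])
        t = members[int(rng.integers(len(members)))]
        npc = np_ids[idx % len(np_ids)]
        pair_set.add((npc, t))
        forced_lt100.add((npc, t))

    pairs = sorted(pair_set)
    evidence_rows = generate_evidence_mixture(pairs, config, rng, classes, forced_lt100)
    # suppress strong CT binding inside opportunity pathways
    for row in evidence_rows:
        if (
            classes[row["compound_id"]] == "CT"
            and row["target_id"] in opp_members
            and row["relation"] == "exact"
            and row["value_nM"]
            and float(row["value_nM"]) < 100.0
        ):
            row["value_nM"] = f"{float(10 ** rng.uniform(2.2, 5.0)):.6g}"
    interactions = pd.DataFrame(
        evidence_rows,
        columns=[
            "compound_id",
            "target_id",
            "source_db",
            "literature_ref_id",
            "assay_type",
            "relation",
            "value_nM",
            "unit",
        ],
    )

    # ---- compound catalog rows (with duplicate source records) ----
    sources = [f"{SOURCE_PREFIX}{i + 1:02d}" for i in range(config.n_sources)]
    cat_rows = []
    for c in compound_ids:
        name = f"{'np' if classes[c] == 'NP' else 'ct'}-compound-{c[2:]}"
        inchikey = f"IK{c}-SYNTH-N"
        smiles = f"SMILES[{c}]"
        cid = str(100000 + int(c[2:]))
        cas = f"{int(c[2:]):05d}-{int(rng.integers(10, 99))}-{int(rng.integers(0, 9))}"
        src1 = sources[int(rng.integers(config.n_sources))]
        cat_rows.append(
            {
                "compound_id": c,
                "class": classes[c],
                "name": name,
                "smiles": smiles,
                "inchikey": inchikey,
                "pubchem_cid": cid,
                "cas": "",
                "source_dbs": src1,
            }
        )
        if rng.random() < config.p_extra_source_record:
            src2 = sources[int(rng.integers(config.n_sources))]
            # second record: overlapping inchikey, name case-jittered, cas only here
            cat_rows.append(
                {
                    "compound_id": c,
                    "class": classes[c],
                    "name": name.upper(),
                    "smiles": "",
                    "inchikey": inchikey,
                    "pubchem_cid": "",
                    "cas": cas,
                    "source_dbs": src2,
                }
            )
    compounds = pd.DataFrame(
        cat_rows,
        columns=["compound_id", "class", "name", "smiles", "inchikey", "pubchem_cid", "cas", "source_dbs"],
    )

    # ---- exclusion list: a few NPs are secretly known drugs ----
    excluded = sorted(
        np_ids[i] for i in rng.choice(len(np_ids), size=config.n_excluded_np, replace=False)
    )
    excl_rows = [
        {
            "name": f"np-compound-{c[2:]}".upper(),  # case-insensitive match exercised
            "smiles": "",
            "inchikey": "",
            "pubchem_cid": "",
            "cas": "",
        }
        for c in excluded
    ]
    excl_rows.append(
        {"name": "decoy-not-in-catalog", "smiles": "", "inchikey": "", "pubchem_cid": "", "cas": ""}
    )
    exclusion = pd.DataFrame(
        excl_rows, columns=["name", "smiles", "inchikey", "pubchem_cid", "cas"]
    )

    # ---- drivers with tumor types ----
    tumor_types = [f"TT{i:02d}" for i in range(1, config.n_tumor_types + 1)]
    drv_rows = []
    for d in drivers:
        k = 1 + int(rng.integers(3))
        tts = sorted(
            tumor_types[i] for i in rng.choice(config.n_tumor_types, size=k, replace=False)
        )
        drv_rows.append({"driver_gene": d, "tumor_types": "|".join(tts)})
    drivers_df = pd.DataFrame(drv_rows, columns=["driver_gene", "tumor_types"])

    families_df = pd.DataFrame(
        [{"target_id": t, "family": target_family[t]} for t in targets],
        columns=["target_id", "family"],
    )

    # ---- write everything ----
    _write_tsv(compounds, outdir / "compounds.tsv")
    _write_tsv(interactions, outdir / "interactions.tsv")
    _write_tsv(hierarchy, outdir / "pathway_hierarchy.tsv")
    ppi = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])
    _write_tsv(ppi, outdir / "ppi.tsv")
    _write_tsv(drivers_df, outdir / "drivers.tsv")
    _write_tsv(families_df, outdir / "families.tsv")
    _write_tsv(exclusion, outdir / "exclusion_list.tsv")
    with open(outdir / "pathways.gmt", "w") as fh:
        for pid in pathway_ids:
            genes = "\t".join(sorted(pathway_sets[pid]))
            fh.write(f"{pid}\tsynthetic pathway {pid}\t{genes}\n")

    truth = ScenarioTruth(
        planted_enriched_pathway_ids=set(planted),
        planted_opportunity_pathway_ids=set(opportunity),
        planted_family_of_compound=dict(compound_family),
        planted_driver_set=driver_set,
        planted_excluded_np_ids=set(excluded),
    )
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_targets": config.n_targets,
        "n_drivers": n_drivers,
        "n_ppi_edges": len(edges),
        "n_compound_records": len(compounds),
        "n_evidence_items": len(interactions),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return truth


def read_gmt(path) -> dict[str, set[str]]:
    """pathway_id TAB description TAB gene... -> {pathway_id: genes}."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


def read_drivers(path) -> dict[str, set[str]]:
    """drivers.tsv -> {driver_gene: set of tumor types}."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        r["driver_gene"]: set(t for t in r["tumor_types"].split("|") if t)
        for _, r in df.iterrows()
    }


def read_families(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return dict(zip(df["target_id"], df["family"]))


def entity_level_pathways(hierarchy_path, pathway_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Subset of pathway sets flagged entity-level in the hierarchy table."""
    df = pd.read_csv(hierarchy_path, sep="\t", dtype={"pathway_id": str, "parent_id": str})
    flagged = set(df.loc[df["entity_level"].astype(int) == 1, "pathway_id"])
    return {p: g for p, g in pathway_sets.items() if p in flagged}
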