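"""End-to-end pipeline: scenario inputs -> report bundle.

Stages run in order: compound integration -> evidence grading -> coverage ->
driver enrichment -> PPI topology -> pathway crosstalk -> compound
communities.  Every stage writes its tables under the output directory and
contributes row/drop counts to a JSON run manifest, so no records are ever
silently dropped.  Outputs are deterministic for a fixed config + seed
(reruns produce byte-identical bundles).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, catalog, communities, coverage, crosstalk, enrichment, evidence, synthetic, topology
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    input_dir: str
    output_dir: str
    thresholds_nM: tuple[float, float] = (100.0, 1000.0)
    enrichment_alpha: float = 0.05
    n_controls: int = 1000
    seed: int = 0
    top_k: int = 10

    def validate(self) -> None:
        from .errors import ConfigError

        if any(t <= 0 for t in self.thresholds_nM):
            raise ConfigError("affinity thresholds must be positive")
        if not (0 < self.enrichment_alpha < 1):
            raise ConfigError("enrichment_alpha must lie in (0, 1)")
        if self.n_controls < 1:
            raise ConfigError("n_controls must be positive")


@dataclass
class PipelineState:
    """Everything later stages need from earlier ones."""

    config: RunConfig
    catalog: catalog.Catalog | None = None
    classes: dict[str, str] = field(default_factory=dict)
    interactions: list = field(default_factory=list)
    pathways: dict[str, set[str]] = field(default_factory=dict)
    driver_tumor: dict[str, set[str]] = field(default_factory=dict)
    driver_set: set[str] = field(default_factory=set)
    enriched: set[str] = field(default_factory=set)
    manifest: dict = field(default_factory=dict)

    @property
    def indir(self) -> Path:
        return Path(self.config.input_dir)

    @property
    def outdir(self) -> Path:
        return Path(self.config.output_dir)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def _read_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def stage_integrate(state: PipelineState) -> None:
    """Merge compound records and scrub NP drugs via the exclusion list."""
    df = _read_tsv(state.indir / "compounds.tsv")
    records = catalog.records_from_frame(df)
    merged = catalog.merge_compounds(records)
    excl = catalog.exclusion_keysets_from_frame(_read_tsv(state.indir / "exclusion_list.tsv"))
    scrubbed, removed = catalog.scrub_drugs(merged, excl)
    state.catalog = scrubbed
    state.classes = scrubbed.classes()
    _write(scrubbed.to_frame(), state.outdir / "catalog.tsv")
    _write(scrubbed.conflicts, state.outdir / "catalog_conflicts.tsv")
    _write(removed, state.outdir / "catalog_removed.tsv")
    state.manifest["integrate"] = {
        "input_records": len(records),
        "merged_compounds": len(merged),
        "scrubbed_compounds": len(scrubbed),
        "removed_compounds": len(removed),
        "key_conflicts": len(merged.conflicts),
    }


def stage_evidence(state: PipelineState) -> None:
    """Grade evidence, aggregate per pair, summarize by class and level."""
    df = _read_tsv(state.indir / "interactions.tsv")
    items = evidence.evidence_from_frame(df)
    id_map = state.catalog.id_map if state.catalog else {}
    kept, dropped = [], 0
    for it in items:
        cid = id_map.get(it.compound_id)
        if cid is None:
            dropped += 1  # compound scrubbed or unknown
            continue
        kept.append(dataclasses.replace(it, compound_id=cid))
    state.interactions = evidence.aggregate_all(kept)
    summaries = evidence.summarize_evidence(state.interactions, state.classes)
    for name, table in summaries.items():
        _write(table, state.outdir / f"evidence_{name}.tsv")
    state.manifest["evidence"] = {
        "input_items": len(items),
        "dropped_items": dropped,
        "kept_items": len(kept),
        "interactions": len(state.interactions),
    }


def _load_annotations(state: PipelineState) -> None:
    state.pathways = synthetic.read_gmt(state.indir / "pathways.gmt")
    state.driver_tumor = synthetic.read_drivers(state.indir / "drivers.tsv")
    state.driver_set = set(state.driver_tumor)


def stage_coverage(state: PipelineState) -> None:
    """Coverage tables over all pathways, plus driver/tumor and KS tables."""
    if not state.pathways:
        _load_annotations(state)
    thr100 = min(state.config.thresholds_nM)
    table_all = coverage.coverage_table(
        state.interactions, state.classes, state.pathways
    )
    _write(table_all, state.outdir / "coverage_all_pathways.tsv")

    # classification dump + within-pathway NP share at the tight threshold
    rows = []
    for name, levels, thr in coverage.DEFAULT_STRATA:
        sel = evidence.select_stratum(state.interactions, levels, thr)
        np_t, ct_t = coverage.hit_targets(sel, state.classes)
        p_labels = coverage.classify_entities(np_t, ct_t, state.pathways)
        rows.extend(
            {"entity_id": p, "label": lab, "stratum": name} for p, lab in sorted(p_labels.items())
        )
    _write(pd.DataFrame(rows), state.outdir / "pathway_classification.tsv")

    sel100 = evidence.select_stratum(
        state.interactions, frozenset(("I", "II", "III")), thr100
    )
    np_t, ct_t = coverage.hit_targets(sel100, state.classes)
    p_labels = coverage.classify_entities(np_t, ct_t, state.pathways)
    t_universe = np_t | ct_t
    t_labels = coverage.classify_entities(np_t, ct_t, {t: {t} for t in t_universe})
    share = None
    if any(v == "BOTH" for v in p_labels.values()):
        share = coverage.within_pathway_interaction_share(p_labels, t_labels, state.pathways)

    tumor = coverage.driver_tumor_coverage(
        state.driver_tumor, state.interactions, state.classes, thr100
    )
    _write(tumor, state.outdir / "driver_tumor_coverage.tsv")
    ks = coverage.per_compound_distributions(
        state.interactions,
        state.classes,
        state.pathways,
        state.driver_tumor,
        thresholds=state.config.thresholds_nM,
    )
    _write(ks, state.outdir / "per_compound_ks.tsv")
    state.manifest["coverage"] = {
        "pathway_universe": len(state.pathways),
        "np_share_in_both_pathways_lt100": share,
        "tumor_types": len(tumor),
        "ks_rows": len(ks),
    }


def stage_enrich(state: PipelineState) -> None:
    """Driver enrichment, cancer-pathway coverage, opportunity pathways."""
    if not state.pathways:
        _load_annotations(state)
    thr100 = min(state.config.thresholds_nM)
    enriched, results = enrichment.aberrational_pathways(
        state.pathways, state.driver_set, alpha=state.config.enrichment_alpha
    )
    state.enriched = enriched
    _write(results, state.outdir / "driver_enrichment.tsv")
    if enriched:
        cancer_sets = {p: state.pathways[p] for p in enriched}
        table_cancer = coverage.coverage_table(
            state.interactions,
            state.classes,
            cancer_sets,
            restrict_targets_to_pathways=True,
        )
        _write(table_cancer, state.outdir / "coverage_cancer_pathways.tsv")
        lt100 = evidence.select_stratum(
            state.interactions, frozenset(("I", "II", "III")), thr100
        )
        opp = enrichment.np_only_opportunity_pathways(
            enriched, state.pathways, lt100, state.classes, state.driver_set
        )
        _write(opp, state.outdir / "opportunity_pathways.tsv")
        n_opp = len(opp)
    else:
        n_opp = 0
    state.manifest["enrich"] = {
        "tested_pathways": len(results),
        "enriched_pathways": len(enriched),
        "opportunity_pathways": n_opp,
    }


def stage_topology(state: PipelineState) -> None:
    """Topology profiles and group comparisons on the PPI network."""
    if not state.driver_set:
        _load_annotations(state)
    thr100 = min(state.config.thresholds_nM)
    graph = topology.load_network(state.indir / "ppi.tsv")
    sel = evidence.select_stratum(
        state.interactions, frozenset(("I", "II", "III")), thr100
    )
    np_t, ct_t = coverage.hit_targets(sel, state.classes)
    profiles = topology.compute_profiles(graph, np_t, ct_t, state.driver_set)
    _write(profiles, state.outdir / "topology_profiles.tsv")
    comp_tables = []
    for measure in ("degree", "betweenness", "eigenvector"):
        comp = topology.compare_groups(profiles, measure, seed=state.config.seed)
        t = comp["pairwise"]
        t.insert(0, "measure", measure)
        comp_tables.append(t)
    dist = topology.compare_groups(
        profiles,
        "mean_dist_to_drivers",
        n_controls=state.config.n_controls,
        seed=state.config.seed,
    )
    t = dist["pairwise"]
    t.insert(0, "measure", "mean_dist_to_drivers")
    comp_tables.append(t)
    _write(pd.concat(comp_tables, ignore_index=True), state.outdir / "topology_group_tests.tsv")
    if dist["controls"] is not None:
        _write(dist["controls"], state.outdir / "topology_distance_controls.tsv")
    _write(
        topology.top_nodes_report(profiles, k=state.config.top_k),
        state.outdir / "topology_top_nodes.tsv",
    )
    state.manifest["topology"] = {
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "targeted_nodes": int((profiles["group"] != "UNTARGETED").sum()),
        "seed": state.config.seed,
        "test": "mannwhitneyu_two_sided",
    }


def stage_crosstalk(state: PipelineState) -> None:
    """Entity-level pathway network, set distances, synergy candidates."""
    if not state.pathways:
        _load_annotations(state)
    if "enrich" not in state.manifest:
        stage_enrich(state)
    thr100 = min(state.config.thresholds_nM)
    entity_sets = synthetic.entity_level_pathways(
        state.indir / "pathway_hierarchy.tsv", state.pathways
    )
    graph = crosstalk.build_pathway_graph(entity_sets)
    sel = evidence.select_stratum(
        state.interactions, frozenset(("I", "II", "III")), thr100
    )
    np_t, ct_t = coverage.hit_targets(sel, state.classes)
    labels = coverage.classify_entities(np_t, ct_t, entity_sets)
    crosstalk.label_nodes(graph, labels, state.enriched)
    edge_rows = [
        {"pathway_a": a, "pathway_b": b, "shared_gene_count": graph.edges[a, b]["weight"]}
        for a, b in sorted(graph.edges())
    ]
    _write(
        pd.DataFrame(edge_rows, columns=["pathway_a", "pathway_b", "shared_gene_count"]),
        state.outdir / "pathway_graph_edges.tsv",
    )
    node_rows = [
        {"pathway_id": p, "label": labels[p], "enriched": p in state.enriched}
        for p in sorted(graph.nodes())
    ]
    _write(pd.DataFrame(node_rows), state.outdir / "pathway_graph_nodes.tsv")

    np_set = {p for p, l in labels.items() if l in ("NP_ONLY", "BOTH")}
    ct_set = {p for p, l in labels.items() if l in ("CT_ONLY", "BOTH")}
    dist_rows = []
    if np_set and ct_set:
        obs = crosstalk.set_distance(graph, np_set, ct_set)
        controls = crosstalk.control_distance(
            graph, len(np_set), len(ct_set), n_reps=state.config.n_controls, seed=state.config.seed
        )
        dist_rows.append(
            {
                "comparison": "NP_covered_vs_CT_covered",
                "mean_distance": obs["mean_distance"],
                "n_pairs": obs["n_pairs"],
                "n_excluded": obs["n_excluded"],
                "empirical_p_vs_random": crosstalk.empirical_p(obs["mean_distance"], controls),
                "n_controls": state.config.n_controls,
            }
        )
    _write(pd.DataFrame(dist_rows), state.outdir / "pathway_set_distances.tsv")

    cands = crosstalk.neighbor_synergy_candidates(graph, entity_sets, np_t, ct_t)
    _write(cands, state.outdir / "synergy_candidates.tsv")
    state.manifest["crosstalk"] = {
        "entity_pathways": len(entity_sets),
        "graph_edges": graph.number_of_edges(),
        "synergy_candidates": len(cands),
        "seed": state.config.seed,
    }


def stage_communities(state: PipelineState) -> None:
    """Shared-target compound network and Louvain communities."""
    thr100 = min(state.config.thresholds_nM)
    graph = communities.build_compound_graph(state.interactions, state.classes, thr100)
    edge_rows = [
        {
            "compound_a": graph.vs[e.source]["name"],
            "compound_b": graph.vs[e.target]["name"],
            "weight": e["weight"],
        }
        for e in graph.es
    ]
    edge_df = pd.DataFrame(edge_rows, columns=["compound_a", "compound_b", "weight"])
    if len(edge_df):
        edge_df = edge_df.sort_values(["compound_a", "compound_b"]).reset_index(drop=True)
    _write(edge_df, state.outdir / "compound_graph_edges.tsv")
    membership, modularity = communities.detect_communities(graph, seed=state.config.seed)
    part_df = pd.DataFrame(
        sorted(membership.items()), columns=["compound_id", "community_id"]
    )
    _write(part_df, state.outdir / "compound_communities.tsv")
    targets_of = communities.qualifying_targets(state.interactions, thr100)
    families = synthetic.read_families(state.indir / "families.tsv")
    report = communities.community_composition(graph, membership, targets_of, families)
    _write(report, state.outdir / "community_report.tsv")
    state.manifest["communities"] = {
        "compounds": graph.vcount(),
        "edges": graph.ecount(),
        "communities": len(set(membership.values())),
        "modularity": None if modularity != modularity else round(modularity, 6),
        "seed": state.config.seed,
    }


STAGES = (
    ("integrate", stage_integrate),
    ("evidence", stage_evidence),
    ("coverage", stage_coverage),
    ("enrich", stage_enrich),
    ("topology", stage_topology),
    ("crosstalk", stage_crosstalk),
    ("communities", stage_communities),
)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the JSON run manifest."""
    config.validate()
    state = PipelineState(config=config)
    state.manifest["npnet_version"] = __version__
    state.manifest["seed"] = config.seed
    state.manifest["thresholds_nM"] = list(config.thresholds_nM)
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            fn(state)
        except Exception as exc:
            raise DataError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_manifest.json").write_text(
        json.dumps(state.manifest, indent=1, sort_keys=True) + "\n"
    )
    return state.manifest
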