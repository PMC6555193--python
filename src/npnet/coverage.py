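"""Coverage classification and comparison of NP vs CT target space.

A target is *covered* by a compound class when at least one interaction in
the selected evidence stratum links a compound of that class to it.  A
pathway is covered when it contains at least one covered target.  Entities
(targets, pathways, PPI nodes, drivers) are classified NP_ONLY / CT_ONLY /
BOTH / NEITHER; note that BOTH at the pathway level only requires the
pathway to intersect both hit sets, not that any single target is hit by
both classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .evidence import Interaction, select_stratum

LABELS = ("NP_ONLY", "CT_ONLY", "BOTH", "NEITHER")

#: The four evidence/affinity strata used throughout the coverage tables.
DEFAULT_STRATA: tuple[tuple[str, frozenset[str], float | None], ...] = (
    ("Evidence levels I, II, III", frozenset({"I", "II", "III"}), None),
    ("Evidence levels II, III", frozenset({"II", "III"}), None),
    ("Evidence levels III", frozenset({"III"}), None),
    ("Evidence level III, binding LT100", frozenset({"III"}), 100.0),
)


def hit_targets(
    interactions: list[Interaction], classes: dict[str, str]
) -> tuple[set[str], set[str]]:
    """(np_targets, ct_targets) covered by the given interactions."""
    np_t: set[str] = set()
    ct_t: set[str] = set()
    for i in interactions:
        (np_t if classes[i.compound_id] == "NP" else ct_t).add(i.target_id)
    return np_t, ct_t


def classify_entities(
    np_targets: set[str],
    ct_targets: set[str],
    membership: dict[str, set[str]],
) -> dict[str, str]:
    """Four-way coverage label for each entity.

    ``membership`` maps an entity to its gene set; for target-level
    classification pass the identity mapping ``{t: {t}}``.
    """
    labels: dict[str, str] = {}
    for entity, genes in membership.items():
        if not genes:
            warnings.warn(f"entity {entity!r} has an empty member set", stacklevel=2)
            labels[entity] = "NEITHER"
            continue
        has_np = not genes.isdisjoint(np_targets)
        has_ct = not genes.isdisjoint(ct_targets)
        if has_np and has_ct:
            labels[entity] = "BOTH"
        elif has_np:
            labels[entity] = "NP_ONLY"
        elif has_ct:
            labels[entity] = "CT_ONLY"
        else:
            labels[entity] = "NEITHER"
    return labels


@dataclass
class CoverageRow:
    stratum: str
    n_targets_np_only: int
    n_targets_ct_only: int
    n_targets_both: int
    n_pathways_np_only: int
    n_pathways_ct_only: int
    n_pathways_both: int
    pct_np_only: float
    pct_ct_only: float
    pct_both: float


def coverage_table(
    interactions: list[Interaction],
    classes: dict[str, str],
    pathways: dict[str, set[str]],
    strata=DEFAULT_STRATA,
    restrict_targets_to_pathways: bool = False,
) -> pd.DataFrame:
    """One coverage row per evidence/affinity stratum.

    Target counts classify individual hit targets; pathway counts and
    percentages classify the supplied pathway universe (pass the
    driver-enriched subset for cancer-pathway tables, with
    ``restrict_targets_to_pathways=True`` so target counts are limited to
    genes of that universe).  Percentages are of the pathway universe,
    rounded to 2 decimals.
    """
    if not pathways:
        raise DataError("coverage_table: empty pathway universe")
    pathway_genes = set().union(*pathways.values()) if pathways else set()
    rows = []
    for name, levels, thr in strata:
        sel = select_stratum(interactions, levels, thr)
        np_t, ct_t = hit_targets(sel, classes)
        if restrict_targets_to_pathways:
            np_t, ct_t = np_t & pathway_genes, ct_t & pathway_genes
        t_universe = np_t | ct_t
        t_labels = classify_entities(np_t, ct_t, {t: {t} for t in t_universe})
        p_labels = classify_entities(np_t, ct_t, pathways)
        tc = pd.Series(list(t_labels.values())).value_counts()
        pc = pd.Series(list(p_labels.values())).value_counts()
        n_univ = len(pathways)
        rows.append(
            CoverageRow(
                stratum=name,
                n_targets_np_only=int(tc.get("NP_ONLY", 0)),
                n_targets_ct_only=int(tc.get("CT_ONLY", 0)),
                n_targets_both=int(tc.get("BOTH", 0)),
                n_pathways_np_only=int(pc.get("NP_ONLY", 0)),
                n_pathways_ct_only=int(pc.get("CT_ONLY", 0)),
                n_pathways_both=int(pc.get("BOTH", 0)),
                pct_np_only=round(100.0 * pc.get("NP_ONLY", 0) / n_univ, 2),
                pct_ct_only=round(100.0 * pc.get("CT_ONLY", 0) / n_univ, 2),
                pct_both=round(100.0 * pc.get("BOTH", 0) / n_univ, 2),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def relative_increase(np_only: int, ct_only: int, both: int) -> float:
    """Percent increase in coverage attributable to NP-only entities.

    100 * np_only / (ct_only + both): the entities covered only once natural
    products are considered, relative to everything the cancer drugs already
    covered.  Callers round to the nearest integer percent for reporting.
    """
    denom = ct_only + both
    if denom <= 0:
        raise DataError("relative_increase undefined: no CT-covered entities")
    return 100.0 * np_only / denom


def within_pathway_interaction_share(
    pathway_labels: dict[str, str],
    target_labels: dict[str, str],
    pathways: dict[str, set[str]],
) -> float:
    """Fraction of covered (pathway, target) pairs in BOTH pathways that are NP-only.

    Over all pairs (p, t) where p is classified BOTH and t is a member of p
    covered in the stratum (target label != NEITHER), returns the fraction
    whose target label is NP_ONLY.
    """
    n_pairs = 0
    n_np_only = 0
    for p, label in pathway_labels.items():
        if label != "BOTH":
            continue
        for t in pathways[p]:
            tl = target_labels.get(t, "NEITHER")
            if tl == "NEITHER":
                continue
            n_pairs += 1
            if tl == "NP_ONLY":
                n_np_only += 1
    if n_pairs == 0:
        raise DataError("no covered targets inside BOTH pathways")
    return n_np_only / n_pairs


def driver_tumor_coverage(
    driver_tumor_types: dict[str, set[str]],
    interactions: list[Interaction],
    classes: dict[str, str],
    threshold_nM: float = 100.0,
) -> pd.DataFrame:
    """Per-tumor-type driver coverage at an exact-affinity threshold.

    For every tumor type: the number of its driver genes targeted only by
    CT drugs, only by NPs, by both, plus its total driver count.  A tumor
    type is "NP-improved" when at least one of its drivers is NP-only.
    """
    sel = select_stratum(interactions, frozenset(("I", "II", "III")), threshold_nM)
    np_t, ct_t = hit_targets(sel, classes)
    labels = classify_entities(np_t, ct_t, {d: {d} for d in driver_tumor_types})
    tumor_rows: dict[str, dict] = {}
    for driver, tts in driver_tumor_types.items():
        for tt in tts:
            row = tumor_rows.setdefault(
                tt, {"tumor_type": tt, "ct_only": 0, "np_only": 0, "both": 0, "total_drivers": 0}
            )
            row["total_drivers"] += 1
            lab = labels[driver]
            if lab == "CT_ONLY":
                row["ct_only"] += 1
            elif lab == "NP_ONLY":
                row["np_only"] += 1
            elif lab == "BOTH":
                row["both"] += 1
    df = pd.DataFrame(sorted(tumor_rows.values(), key=lambda r: r["tumor_type"]))
    if not df.empty:
        df["np_improved"] = df["np_only"] >= 1
    return df


def per_compound_counts(
    interactions: list[Interaction],
    classes: dict[str, str],
    pathways: dict[str, set[str]],
    driver_tumor_types: dict[str, set[str]],
    threshold_nM: float,
    cancer_pathways: dict[str, set[str]] | None = None,
    include_zero: bool = False,
) -> dict[str, dict[str, list[int]]]:
    """Per-compound counts of covered entities, split by compound class.

    Entities counted per compound: distinct qualifying targets, pathways
    containing at least one of those targets (all pathways and, when given,
    the cancer subset), tumor types of targeted drivers, and drivers.  Only
    interactions with an exact value < threshold qualify.  Compounds with no
    qualifying interaction are excluded unless ``include_zero``.
    """
    sel = select_stratum(interactions, frozenset(("I", "II", "III")), threshold_nM)
    targets_of: dict[str, set[str]] = {}
    for i in sel:
        targets_of.setdefault(i.compound_id, set()).add(i.target_id)
    if include_zero:
        for c in classes:
            targets_of.setdefault(c, set())

    gene_to_pathways: dict[str, set[str]] = {}
    for p, genes in pathways.items():
        for g in genes:
            gene_to_pathways.setdefault(g, set()).add(p)
    gene_to_cancer: dict[str, set[str]] = {}
    if cancer_pathways:
        for p, genes in cancer_pathways.items():
            for g in genes:
                gene_to_cancer.setdefault(g, set()).add(p)

    out: dict[str, dict[str, list[int]]] = {}
    kinds = ["targets", "pathways", "tumor_types", "drivers"]
    if cancer_pathways is not None:
        kinds.append("cancer_pathways")
    for kind in kinds:
        out[kind] = {"NP": [], "CT": []}
    for cid in sorted(targets_of):
        ts = targets_of[cid]
        cls = classes[cid]
        pws = set().union(*(gene_to_pathways.get(t, set()) for t in ts)) if ts else set()
        drivers = {t for t in ts if t in driver_tumor_types}
        tts = set().union(*(driver_tumor_types[d] for d in drivers)) if drivers else set()
        out["targets"][cls].append(len(ts))
        out["pathways"][cls].append(len(pws))
        out["tumor_types"][cls].append(len(tts))
        out["drivers"][cls].append(len(drivers))
        if cancer_pathways is not None:
            cpws = set().union(*(gene_to_cancer.get(t, set()) for t in ts)) if ts else set()
            out["cancer_pathways"][cls].append(len(cpws))
    return out


def ks_compare(np_sample: list[int], ct_sample: list[int]) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value."""
    res = stats.ks_2samp(
        np.asarray(np_sample, dtype=float),
        np.asarray(ct_sample, dtype=float),
        alternative="two-sided",
        method="asymp",
    )
    return float(res.statistic), float(res.pvalue)


def per_compound_distributions(
    interactions: list[Interaction],
    classes: dict[str, str],
    pathways: dict[str, set[str]],
    driver_tumor_types: dict[str, set[str]],
    thresholds: tuple[float, ...] = (100.0, 1000.0),
    cancer_pathways: dict[str, set[str]] | None = None,
    include_zero: bool = False,
    alpha_bonferroni: float = 0.004,
) -> pd.DataFrame:
    """Compare per-compound NP vs CT count distributions with the KS test.

    One row per (entity kind, threshold): medians, the two-sample KS D and
    asymptotic p-value, and a significance flag at the Bonferroni-adjusted
    threshold (0.004 by default).  Comparisons where either class has fewer
    than two qualifying compounds are skipped with a warning.
    """
    rows = []
    for thr in thresholds:
        dists = per_compound_counts(
            interactions, classes, pathways, driver_tumor_types, thr,
            cancer_pathways=cancer_pathways, include_zero=include_zero,
        )
        for kind, samples in dists.items():
            np_s, ct_s = samples["NP"], samples["CT"]
            if len(np_s) < 2 or len(ct_s) < 2:
                warnings.warn(
                    f"{kind} at <{thr:g} nM: fewer than 2 qualifying compounds "
                    "in a class; comparison skipped",
                    stacklevel=2,
                )
                continue
            d, p = ks_compare(np_s, ct_s)
            rows.append(
                {
                    "kind": kind,
                    "threshold_nM": thr,
                    "n_np": len(np_s),
                    "n_ct": len(ct_s),
                    "median_np": float(np.median(np_s)),
                    "median_ct": float(np.median(ct_s)),
                    "ks_D": d,
                    "p_value": p,
                    "significant": p < alpha_bonferroni,
                }
            )
    return pd.DataFrame(rows)
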