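"""Driver-gene over-representation and NP-only opportunity pathways.

Pathways enriched for cancer driver genes ("pan-cancer aberrational"
pathways) are found with an upper-tail hypergeometric test per pathway and
the Benjamini-Yekutieli step-up adjustment, which controls the false
discovery rate under arbitrary dependence between the per-pathway tests
(pathways share genes, so the tests are far from independent).

An *opportunity* pathway is a driver-enriched pathway with no CT drug
interaction below 100 nM but at least one NP interaction below 100 nM — a
place where only a natural product currently reaches clinically relevant
binding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import hit_targets
from .errors import DataError
from .evidence import Interaction

log = logging.getLogger(__name__)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N):
        raise DataError(f"invalid hypergeometric arguments: k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise DataError(f"invalid hypergeometric arguments: k={k}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values, in input order.

    Sorted ascending, raw_i = p_(i) * m * c(m) / i with the harmonic
    correction c(m) = sum_{j<=m} 1/j, made monotone non-decreasing from the
    largest down and clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def aberrational_pathways(
    pathways: dict[str, set[str]],
    driver_set: set[str],
    alpha: float = 0.05,
    universe: set[str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Driver-enriched pathway set plus the full per-pathway results.

    The gene universe defaults to the union of all pathway genes; drivers
    absent from the universe are dropped from K (logged).  A pathway is
    enriched when its BY q-value is below alpha.
    """
    if not driver_set:
        raise DataError("aberrational_pathways: empty driver set")
    if not pathways:
        raise DataError("aberrational_pathways: no pathways supplied")
    if universe is None:
        universe = set().union(*pathways.values())
    drivers_in = driver_set & universe
    dropped = len(driver_set) - len(drivers_in)
    if dropped:
        log.info("dropped %d drivers absent from the gene universe", dropped)
    if not drivers_in:
        raise DataError("no driver genes present in the gene universe")
    N, K = len(universe), len(drivers_in)

    rows = []
    for pid in sorted(pathways):
        genes = pathways[pid] & universe
        n = len(genes)
        k = len(genes & drivers_in)
        p = hypergeom_pvalue(k, n, K, N) if n else 1.0
        rows.append({"pathway_id": pid, "k": k, "n": n, "K": K, "N": N, "p_value": p})
    df = pd.DataFrame(rows)
    df["q_value"] = by_adjust(df["p_value"].to_numpy())
    df["enriched"] = df["q_value"] < alpha
    enriched = set(df.loc[df["enriched"], "pathway_id"])
    return enriched, df


def np_only_opportunity_pathways(
    enriched_ids: set[str],
    pathways: dict[str, set[str]],
    interactions_lt100: list[Interaction],
    classes: dict[str, str],
    driver_set: set[str],
) -> pd.DataFrame:
    """Enriched pathways reachable (<100 nM) only through natural products.

    ``interactions_lt100`` must already be filtered to exact values below
    100 nM.  Each returned pathway lists the NP targets and compounds
    involved and whether any NP target is itself a cancer driver (the two
    patterns of interest: hitting the driver directly vs hitting a non-driver
    member of a driver-enriched pathway).
    """
    np_t, ct_t = hit_targets(interactions_lt100, classes)
    np_compounds_of: dict[str, set[str]] = {}
    for i in interactions_lt100:
        if classes[i.compound_id] == "NP":
            np_compounds_of.setdefault(i.target_id, set()).add(i.compound_id)

    rows = []
    for pid in sorted(enriched_ids):
        genes = pathways[pid]
        ct_hits = genes & ct_t
        np_hits = genes & np_t
        if ct_hits or not np_hits:
            continue
        compounds = sorted(set().union(*(np_compounds_of[t] for t in np_hits)))
        rows.append(
            {
                "pathway_id": pid,
                "n_np_targets": len(np_hits),
                "np_targets": "|".join(sorted(np_hits)),
                "np_compounds": "|".join(compounds),
                "np_target_is_driver": bool(np_hits & driver_set),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "n_np_targets",
            "np_targets",
            "np_compounds",
            "np_target_is_driver",
        ],
    )
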