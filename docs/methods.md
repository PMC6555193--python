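# Methods

## Problem and model

The package compares two compound classes — natural products (NP) and
approved antineoplastic drugs (CT) — by the biological entities their
high-confidence targets reach. The underlying model is deliberately simple
and auditable:

* An **evidence item** is one database entry supporting a compound–target
  pair. Its grade is a pure function of two booleans: Level III iff it has
  both a literature reference and an experimental binding value, Level II
  iff a reference only, Level I otherwise. A value reported by a source
  whose reference linkage is inaccessible therefore stays Level I — grading
  reflects *accessible* support, not presumed support.
* An **interaction** (one compound–target pair) takes the maximum grade over
  its items and, as its binding value, the minimum over items with an
  *exact* value. Minimum = most potent; this is conservative with respect to
  a "< threshold" rule, since any qualifying assay admits the pair.
  Relation-qualified values ("<", ">") never qualify: a "< 100 nM" bound is
  not an exact measurement, and admitting it would make the threshold rule
  circular.
* **Coverage** of an entity (target, pathway, driver, tumor type, PPI node)
  by a class requires ≥ 1 interaction of that class in the selected
  evidence/affinity stratum on one of the entity's genes. A pathway is BOTH
  when it intersects both hit sets — a single co-hit target is *not*
  required, which matters because pathway-level overlap can be high while
  target-level overlap is tiny.
* The headline statistic, `100 × NP_only / (CT_only + Both)`, reads as "how
  much the covered universe grows when NP targets are admitted, relative to
  what drugs already cover". It is scale-invariant in the three counts and
  undefined (an explicit error) when drugs cover nothing.

## Statistics

* **Driver over-representation**: upper-tail hypergeometric P(X ≥ k) with
  population N = union of genes over all supplied pathways (the natural
  closed world of the input bundle; an explicit universe can be supplied
  instead), K = drivers inside that universe (drivers outside it are dropped
  with a logged count), n = pathway size, k = drivers in the pathway.
  Inclusive P(X ≥ k) is used rather than P(X > k). FDR control is
  Benjamini–Yekutieli (step-up with harmonic correction c(m) = Σ 1/i),
  chosen because pathway tests are dependent through shared genes; α = 0.05.
* **Distribution comparisons** (per-compound counts of targets, pathways,
  tumor types, drivers): two-sided two-sample Kolmogorov–Smirnov with
  asymptotic p-values; significance at the Bonferroni-adjusted 0.004.
  Compounds with zero qualifying interactions are excluded from the samples
  by default (configurable), since "compounds with a sub-threshold target"
  is the natural sampling frame at each threshold.
* **Group topology comparisons**: two-sided Mann–Whitney U — centrality
  distributions are heavy-tailed, so a rank test rather than a t-test; the
  choice is recorded in the output metadata. Distance-to-driver group means
  are additionally compared with size-matched uniform random node sets
  (default 1000), p = (1 + #{controls ≤ observed}) / (n + 1); controls are
  not degree-matched by design.
* **Community enrichment**: per-community two-sided Fisher exact test on the
  2×2 (community membership × class) table — counts are small, so an exact
  test.

## Numerical choices

* Betweenness is exact (Brandes), unnormalized, each unordered source–target
  pair counted once with fractional credit over tied shortest paths.
* Eigenvector centrality is a power iteration on A + I to elementwise
  tolerance 1e-10 (≤ 1000 iterations), then max-normalized so the top node
  scores 1. The +I shift keeps the principal eigenvector while making the
  dominant eigenvalue strict, so bipartite components cannot oscillate; on
  disconnected graphs scores outside the dominant component decay toward 0,
  matching common library behavior. Non-convergence raises an error naming
  the offending component. An edgeless graph gets all-zero scores.
* Mean distance to drivers averages per node over reachable drivers (self
  excluded for drivers); nodes with no reachable driver are undefined and
  excluded from group means. Pooling pairs instead would weight large
  components more; the per-node-then-group convention was chosen and is
  applied consistently.
* Pathway-crosstalk distances are hop counts on the unweighted shared-gene
  graph; edge weights (shared-gene counts) are reported but do not enter
  paths. Cross-component pairs are excluded from means and their count
  reported, rather than assigned infinity.
* Louvain community detection uses igraph's multilevel algorithm on edge
  weights at resolution 1.0; the vertex-visit order is fixed by a recorded
  seed because greedy modularity optimization is order-sensitive.
* Compound-key matching normalizes names by lowercasing, trimming and
  collapsing internal whitespace; other keys compare verbatim. No synonym
  expansion or SMILES canonicalization — synonym lists are curated inputs,
  and structure standardization is out of scope. Conflicting key values
  within a merged compound are retained multi-valued and flagged, not fatal.
  NP and CT records never merge with each other: a compound's class is part
  of its curated identity, and cross-class collisions are exactly what the
  scrubbing step is for.
* All binding values must arrive in nM; rows with any other unit are
  rejected rather than converted (source unit chaos is upstream curation,
  not pipeline logic).
* Table percentages are rounded to 2 decimals; headline relative increases
  to the nearest integer percent.

## Synthetic scenarios: what they emulate and what they do not

`ScenarioConfig` defaults define the study conditions: 500 targets in 20
protein families, 15% drivers, 60 pathways of 10–40 genes (half
entity-level leaves of a random pathway forest), 150 NP + 50 CT compounds,
7 evidence sources, literature-reference probability 0.5, binding-value
probability 0.4, log10 affinities Normal(2.0, 1.5) in nM (median 100 nM
with a pM–mM spread, a realistic range for public binding data), ~5 targets
per compound with an 8× odds bias toward the compound's own family, 15% of
values relation-qualified, and a PPI with within-pathway edge probability
0.08 over background 0.004 plus 10 extra random edges per driver.

Planted structure, recorded in `truth.json`:

* 8 driver-enriched pathways draw ≥ 70% of members from the driver set
  (safely above the 60% floor the generator guarantees and far above the
  15% background), so over-representation is recoverable;
* 3 of them are opportunity pathways: one guaranteed NP item with a
  reference and an exact value < 100 nM, and every CT exact value < 100 nM
  on their members is resampled upward — the NP-only condition holds by
  construction;
* driver nodes receive extra random PPI edges, making the driver vs
  non-driver degree/betweenness contrast recoverable;
* a handful of NP compounds are planted on the exclusion list (scrubbing),
  and compounds appear as 1–2 source records sharing an InChIKey with
  case-jittered names (merging).

Deliberately **not** emulated: real chemical structures (SMILES are
placeholder tokens), text-mining noise, unit heterogeneity, correlations
between affinity and topology, and any bias of targeted nodes toward hubs.
Consequently, passing recovery tests shows the pipeline detects the
structures it is designed to detect at realistic scale — it does not show
that targeted nodes in real PPI networks are more central, and on synthetic
data the NP/CT topology groups are statistically indistinguishable, as they
should be under this null.

Determinism contract: identical config + seed give byte-identical files
(single RNG stream, fixed iteration order, fixed float formatting);
different seeds change checksums.

## Scale of the shipped analyses

The checked-in analyses and tests run the default scenario (500 targets,
200 compounds) and smaller variants; enrichment-recovery statistics pool 20
seeds and community recovery 10 seeds. These sizes give stable pass/fail
behaviour for the planted effect sizes while keeping any single analysis in
seconds. Larger scenarios are a config change, not a code change.

## Known limitations

* Evidence Level I conflates "entry in one database" with "entries in many
  databases, none with accessible support" — faithful to the grading
  framework, but a count-aware grade could separate them.
* The hypergeometric universe excludes genes not in any pathway; enrichment
  q-values therefore depend on pathway-collection completeness.
* The spec-level claim that synergy-candidate counts shrink monotonically as
  the affinity threshold tightens is not a theorem (a pathway can flip from
  BOTH to NP_ONLY and create candidates); the implementation reports
  whatever the labels give, and tests assert only the sound properties.
* Empirical control p-values are bounded below by 1/(n_controls + 1);
  claims below ~0.001 need more replicates than the default 1000.
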