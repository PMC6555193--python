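#!/usr/bin/env python
"""PPI topology of NP- and drug-targeted nodes vs the rest of the network.

Profiles every PPI node (degree, betweenness, eigenvector centrality, mean
distance to driver genes), compares the coverage groups with Mann-Whitney
tests, compares driver-distance means with random size-matched node sets,
and lists the top-ranked nodes per group and measure.
"""

from pathlib import Path

import pandas as pd

from npnet.pipeline import (
    PipelineState,
    RunConfig,
    stage_evidence,
    stage_integrate,
    stage_topology,
)

SCENARIO_DIR = Path("results/scenario")
OUT_DIR = Path("results/pipeline")


def main() -> None:
    state = PipelineState(
        config=RunConfig(input_dir=str(SCENARIO_DIR), output_dir=str(OUT_DIR), seed=1)
    )
    stage_integrate(state)
    stage_evidence(state)
    stage_topology(state)

    prof = pd.read_csv(OUT_DIR / "topology_profiles.tsv", sep="\t")
    print("median degree / betweenness by group:")
    med = prof.groupby("group")[["degree", "betweenness"]].median()
    print(med.to_string())
    drv = prof.groupby("is_driver")[["degree", "betweenness"]].median()
    print("\nmedian degree / betweenness, drivers vs non-drivers:")
    print(drv.to_string())
    tests = pd.read_csv(OUT_DIR / "topology_group_tests.tsv", sep="\t")
    print("\npairwise Mann-Whitney tests:")
    print(tests.to_string(index=False))
    controls = OUT_DIR / "topology_distance_controls.tsv"
    if controls.exists():
        print("\ndistance-to-driver vs random node sets:")
        print(pd.read_csv(controls, sep="\t").to_string(index=False))


if __name__ == "__main__":
    main()
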