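#!/usr/bin/env python
"""Behavioral learning-index analysis of the synthetic choice-assay
cohort: per-pair preference and learning indices, one-way ANOVA with
Tukey post-hoc tests across genotype × temperature groups, and
Bonferroni-corrected one-sample t-tests against 0.

Expected pattern: groups with γ1 or γ5 output blocked at restrictive
temperature have learning indices indistinguishable from 0; all other
groups show significant learned avoidance (negative LI).

Writes results/learning_indices.csv, results/behavior_one_sample.csv,
results/behavior_tukey.csv, results/behavior_anova.json.
"""

import json
from pathlib import Path

from mbondecode import behavior as bh
from mbondecode import io as mio

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lanes = mio.read_table(OUT / "behavior_lanes.csv", mio.LANE_SCHEMA,
                           "lane table")
    indices = bh.lane_indices(lanes)
    tests = bh.behavior_group_tests(indices)
    print(tests["one_sample"].to_string(index=False))
    print(
        f"\nANOVA: F = {tests['anova']['F']:.3f}, p = {tests['anova']['p']:.3g} "
        f"across {tests['anova']['n_groups']} groups"
    )
    mio.write_table(indices, OUT / "learning_indices.csv")
    mio.write_table(tests["one_sample"], OUT / "behavior_one_sample.csv")
    mio.write_table(tests["tukey"], OUT / "behavior_tukey.csv")
    (OUT / "behavior_anova.json").write_text(json.dumps(tests["anova"], indent=2))
    print(f"wrote behavior tables to {OUT}")


if __name__ == "__main__":
    main()
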