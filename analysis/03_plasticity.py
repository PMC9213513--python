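#!/usr/bin/env python
"""Paired pre/post plasticity statistics per compartment, protocol and CS
role, plus the pooled shock-only test on the γ1 MBON.

Expected pattern on default synthetic data: a significant CS+-specific
decrease confined to γ1 after paired training; significant generalized
decreases in γ2–γ4 after paired and odor-only protocols; and a
significant pooled increase in γ1 after shock only, with the per-odor
tests at n = 10 usually not significant.

Writes results/plasticity.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from mbondecode import io as mio
from mbondecode.plasticity import pooled_us_only_test, pre_post_comparison

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    aucs = mio.read_table(OUT / "aucs.csv", mio.AUC_SCHEMA, "AUC table")
    table = pre_post_comparison(aucs)
    pooled = pooled_us_only_test(aucs)
    print(table.to_string(index=False))
    print(
        f"\npooled shock-only gamma1 test: n={pooled.n}, z={pooled.z:.3f}, "
        f"p={pooled.p:.4g}, direction={pooled.direction}"
    )
    table = pd.concat(
        [table, pd.DataFrame([dataclasses.asdict(pooled)])], ignore_index=True
    )
    mio.write_table(table, OUT / "plasticity.csv")
    print(f"wrote {OUT / 'plasticity.csv'}")


if __name__ == "__main__":
    main()
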