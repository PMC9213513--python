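#!/usr/bin/env python
"""Generate the default synthetic dataset: one full imaging experiment
(3 protocols × 5 MBON types × 10 flies × 3 odors × 2 phases = 900 traces)
and a behavioral cohort (5 blocking lines × 2 temperatures × 8 reciprocal
lane pairs).

Writes results/traces.csv, results/behavior_lanes.csv, results/manifest.json.
"""

from pathlib import Path

from mbondecode import io as mio
from mbondecode.config import RunConfig
from mbondecode.synthetic import simulate_behavior, simulate_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = RunConfig()
    cfg.generator.seed = SEED
    cfg.behavior.seed = SEED
    h = mio.write_manifest(OUT / "manifest.json", cfg.to_dict(), SEED)
    traces = simulate_experiment(cfg.generator)
    mio.write_table(mio.traces_to_frame(traces), OUT / "traces.csv",
                    seed=SEED, cfg_hash=h)
    lanes = simulate_behavior(cfg.behavior)
    mio.write_table(lanes, OUT / "behavior_lanes.csv", seed=SEED, cfg_hash=h)
    print(f"wrote {len(traces)} traces ({traces[0].times.size} frames each) "
          f"and {len(lanes)} behavior lanes to {OUT}")


if __name__ == "__main__":
    main()
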