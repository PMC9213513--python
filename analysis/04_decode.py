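#!/usr/bin/env python
"""Pseudo-population SVM decoding: trained condition, the three
chance-level controls, and the five leave-one-MBON-out ablations
(1000 bootstrap draws, 100 models each).

Expected pattern: the trained decoder is significantly above the 50%
chance level; pre-training, odor-only and shock-only controls are near
chance; and among the ablations only removing γ1 pulls accuracy back to
chance.  Note that one run's mean accuracy carries a ~±10-point
dataset-level fluctuation (all models share one 50-animal dataset);
scripts/acceptance.py averages over replicate experiments for the
chance-level quantities.

Writes results/decoding_models.csv and results/decoding_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mbondecode import io as mio
from mbondecode.config import DecodingConfig
from mbondecode.decoding import summarize_results
from mbondecode.pipeline import decode_all_conditions

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    aucs = mio.read_table(OUT / "aucs.csv", mio.AUC_SCHEMA, "AUC table")
    cfg = DecodingConfig(seed=SEED)
    results = decode_all_conditions(aucs, cfg)
    summary = summarize_results(results)
    print(summary.to_string(index=False))
    models = pd.concat(
        [
            pd.DataFrame(
                {
                    "condition": name,
                    "model": np.arange(res.n_models),
                    "accuracy": res.per_model_accuracy,
                }
            )
            for name, res in results.items()
        ],
        ignore_index=True,
    )
    h = mio.config_hash(cfg.to_dict())
    mio.write_table(models, OUT / "decoding_models.csv", seed=SEED, cfg_hash=h)
    (OUT / "decoding_summary.json").write_text(
        json.dumps(
            {"seed": SEED, "config_hash": h,
             "conditions": summary.to_dict(orient="records")},
            indent=2,
        )
    )
    print(f"wrote {OUT / 'decoding_summary.json'}")


if __name__ == "__main__":
    main()
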