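"""End-to-end condition assembly: simulate → quantify → decode.

Thin orchestration over the library modules; the CLI, the analysis
drivers and the reproduction script all go through these helpers so that
a single master seed pins down every pipeline output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mbondecode.config import DecodingConfig, GeneratorConfig
from mbondecode.decoding import (
    DecodingResult,
    ablate_and_decode,
    build_animal_samples,
    relabel_control,
    run_decoding,
)
from mbondecode.synthetic import simulate_experiment
from mbondecode.traces import normalize_aucs, quantify_traces


def quantified_experiment(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate an experiment and return its normalized AUC table."""
    traces = simulate_experiment(config)
    aucs = quantify_traces(traces)
    return normalize_aucs(aucs)


def _relabel_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def decode_all_conditions(
    aucs: pd.DataFrame, config: DecodingConfig
) -> dict[str, DecodingResult]:
    """Run the trained decoder, the three chance-level controls and the
    five leave-one-MBON-out ablations on one normalized AUC table.

    Returns nine named results: ``trained``, ``pretraining``,
    ``odor_only``, ``shock_only`` and ``excl_<mbon>`` for each included
    MBON type.
    """
    results: dict[str, DecodingResult] = {}

    trained = build_animal_samples(aucs, phase="post", protocol="paired")
    results["trained"] = run_decoding(trained, config)

    pre = build_animal_samples(aucs, phase="pre", protocol="paired")
    results["pretraining"] = run_decoding(
        relabel_control(pre, "pretraining"), config
    )

    for tag, mode in enumerate(("odor_only", "shock_only"), start=1):
        ctrl = build_animal_samples(aucs, phase="post", protocol=mode)
        relabeled = relabel_control(ctrl, mode, _relabel_rng(config.seed, tag))
        results[mode] = run_decoding(relabeled, config)

    for excluded, res in ablate_and_decode(trained, config).items():
        results[f"excl_{excluded}"] = res
    return results
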