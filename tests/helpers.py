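"""Shared simulation helpers for calibration/power tests."""

from __future__ import annotations

import numpy as np

from mbondecode.config import DecodingConfig, GeneratorConfig
from mbondecode.decoding import build_animal_samples, run_decoding
from mbondecode.pipeline import quantified_experiment
from mbondecode.plasticity import pre_post_comparison


def g1_experiment(seed: int, plasticity: dict | None, **overrides) -> GeneratorConfig:
    """Small paired-protocol experiment restricted to the γ1 compartment."""
    kwargs = dict(
        mbon_types=("g1",),
        protocols=("paired",),
        odors=("MCH", "OCT3"),
        seed=seed,
    )
    if plasticity is not None:
        kwargs["plasticity"] = plasticity
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def g1_csplus_rejection_rate(
    n_sims: int, base_seed: int, multiplier: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Fraction of simulated experiments in which the γ1 CS+ pre/post test
    rejects, and the fraction rejecting with direction 'decrease'."""
    reject = 0
    reject_decrease = 0
    for i in range(n_sims):
        plast = {("paired", "g1", "CSplus"): multiplier}
        aucs = quantified_experiment(g1_experiment(base_seed + i, plast))
        res = pre_post_comparison(aucs)
        row = res[(res.cs_role == "CSplus")].iloc[0]
        if row.p <= alpha:
            reject += 1
            if row.direction == "decrease":
                reject_decrease += 1
    return reject / n_sims, reject_decrease / n_sims


def replicate_decoding_means(
    n_replicates: int,
    base_seed: int,
    condition_fn,
    n_models: int = 100,
    n_draws: int = 300,
    included_mbons=("g1", "g2", "g3", "g4", "g5"),
) -> np.ndarray:
    """Mean accuracy per replicate experiment for one decoding condition.

    ``condition_fn(aucs, seed)`` must return the AnimalSample collection to
    decode for one replicate.
    """
    means = []
    for i in range(n_replicates):
        seed = base_seed + i
        aucs = quantified_experiment(GeneratorConfig(seed=seed))
        samples = condition_fn(aucs, seed)
        cfg = DecodingConfig(
            seed=seed, n_models=n_models, n_bootstrap_draws=n_draws,
            included_mbons=included_mbons,
        )
        means.append(run_decoding(samples, cfg).mean_accuracy)
    return np.array(means)


def trained_samples(aucs, seed):
    return build_animal_samples(aucs, phase="post", protocol="paired")
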