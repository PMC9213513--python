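"""Synthetic imaging experiments and behavioral cohorts.

The generator emulates the statistical structure of compartment-resolved
postsynaptic calcium imaging in the fly mushroom-body gamma lobe:
heterogeneous per-compartment response amplitudes (γ3 ≫ γ1, γ5 mostly
silent, γ2 biased toward MCH), multiplicative per-animal variability
shared between the pre- and post-training phase, and a configurable
plasticity pattern applied as post/pre amplitude ratios — CS+-confined
suppression in γ1 after associative training, generalized adaptation in
γ2–γ4 after prolonged odor exposure, and a slight γ1 potentiation after
shock alone.

Single transients are a difference-of-exponentials kernel, normalized to
unit peak so that the configured amplitude is the peak ΔF/F₀ of the
noiseless response.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from mbondecode.config import BehaviorConfig, ConfigError, GeneratorConfig
from mbondecode.traces import FluorescenceTrace


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the maximum of ``exp(-t/decay) - exp(-t/rise)`` (closed form)."""
    return (
        rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    )


def response_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient, zero before t = 0."""
    t = np.asarray(t, dtype=float)
    raw = np.where(
        t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0
    )
    t_peak = kernel_peak_time(rise_tau, decay_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    return raw / peak


def simulate_trace(
    config: GeneratorConfig,
    amplitude: float,
    rng: np.random.Generator,
    *,
    fly_id: str = "fly00",
    mbon_type: str = "g1",
    odor: str = "MCH",
    phase: str = "pre",
    protocol: str = "paired",
    cs_role: str = "CSplus",
) -> FluorescenceTrace:
    """Simulate one raw fluorescence trace.

    The trace is ``baseline_F · (1 + amplitude · k(t − onset))`` plus
    additive Gaussian noise of SD ``trial_noise_sd``, sampled on the
    configured frame grid; ``k`` is the unit-peak response kernel, so
    ``amplitude`` is the peak ΔF/F₀ of the noiseless response.
    Deterministic given the generator state.
    """
    if not math.isfinite(amplitude) or amplitude < 0:
        raise ConfigError("amplitude must be finite and >= 0")
    n_frames = int(round(config.trace_duration * config.frame_rate)) + 1
    times = np.arange(n_frames, dtype=float) / config.frame_rate
    kernel = response_kernel(
        times - config.onset_time, config.kernel_rise_tau, config.kernel_decay_tau
    )
    values = config.baseline_F * (1.0 + amplitude * kernel)
    if config.trial_noise_sd > 0:
        values = values + rng.normal(0.0, config.trial_noise_sd, n_frames)
    values = np.maximum(values, 1e-9)  # fluorescence is positive
    return FluorescenceTrace(
        fly_id=fly_id, mbon_type=mbon_type, odor=odor, phase=phase,
        protocol=protocol, cs_role=cs_role, times=times, values=values,
        onset_time=config.onset_time,
    )


def _cs_roles(config: GeneratorConfig, fly_index: int, rng: np.random.Generator) -> dict:
    """Map each odor to its CS role for one fly.

    With counterbalancing on, even-indexed flies get the first trained odor
    as CS+ and odd-indexed flies the second; otherwise the assignment is
    random.  Any further odors are untrained control odors.
    """
    plus, minus = config.trained_odors
    if config.cs_counterbalance:
        if fly_index % 2 == 1:
            plus, minus = minus, plus
    elif rng.random() < 0.5:
        plus, minus = minus, plus
    roles = {odor: "control_odor" for odor in config.odors}
    roles[plus] = "CSplus"
    roles[minus] = "CSminus"
    return roles


def simulate_experiment(config: GeneratorConfig) -> list[FluorescenceTrace]:
    """Simulate the full factorial imaging design.

    One trace per protocol × MBON type × fly × odor × phase.  Each fly is
    imaged in a single MBON type under a single protocol (cohorts are
    per-MBON, per-protocol, as in the real experiments).  Per fly × odor a
    lognormal amplitude factor and a responder indicator are drawn once and
    shared between phases, so the pre/post pairing is informative; the
    post-phase amplitude is the pre-phase amplitude times the configured
    plasticity ratio for (protocol, MBON, CS role), times a lognormal
    session jitter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    traces: list[FluorescenceTrace] = []
    for protocol in config.protocols:
        for mbon in config.mbon_types:
            p_resp = config.responder_probability.get(mbon, 1.0)
            for i in range(config.n_flies_per_group):
                fly_id = f"{protocol}_{mbon}_f{i:03d}"
                roles = _cs_roles(config, i, rng)
                for odor in config.odors:
                    role = roles[odor]
                    responds = rng.random() < p_resp
                    fly_factor = rng.lognormal(0.0, config.fly_effect_sd)
                    base_amp = config.amplitudes.get((mbon, odor), 0.0)
                    pre_amp = base_amp * fly_factor if responds else 0.0
                    ratio = config.plasticity.get((protocol, mbon, role), 1.0)
                    jitter = (
                        rng.lognormal(0.0, config.plasticity_jitter_sd)
                        if config.plasticity_jitter_sd > 0
                        else 1.0
                    )
                    post_amp = pre_amp * ratio * jitter
                    for phase, amp in (("pre", pre_amp), ("post", post_amp)):
                        traces.append(
                            simulate_trace(
                                config, amp, rng,
                                fly_id=fly_id, mbon_type=mbon, odor=odor,
                                phase=phase, protocol=protocol, cs_role=role,
                            )
                        )
    return traces


def simulate_behavior(config: BehaviorConfig) -> pd.DataFrame:
    """Simulate choice-assay lane counts for every configured group.

    Each group contributes ``n_lanes_per_group`` reciprocal lane pairs of
    ``flies_per_lane`` flies.  A pair's target learning index is drawn from
    Normal(mean, LI_sd) — mean 0 for blocked groups, ``mean_LI_learning``
    otherwise — and split into the two lanes' preference indices with an
    optional innate odor bias of opposite sign in the two reciprocal lanes
    (the bias cancels in the learning index).  Preference indices are
    realized as integer fly counts, which truncates them to [-1, 1].

    Returns a lane-level table with columns
    (genotype, temperature, pair, reciprocal_id, n_csplus_side,
    n_csminus_side).
    """
    config.validate()
    if abs(config.mean_LI_learning) + 3.0 * config.LI_sd > 1.0:
        warnings.warn(
            "mean_LI_learning +/- 3 SD exceeds the [-1, 1] range; count "
            "truncation will distort the learning-index distribution",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    for genotype, temperature in config.groups:
        blocked = (genotype, temperature) in config.blocked_groups
        mean_li = 0.0 if blocked else config.mean_LI_learning
        for pair in range(config.n_lanes_per_group):
            li = rng.normal(mean_li, config.LI_sd) if config.LI_sd > 0 else mean_li
            for reciprocal_id, bias_sign in (("A", 1.0), ("B", -1.0)):
                pi = np.clip(li + bias_sign * config.odor_bias, -1.0, 1.0)
                n_plus = int(round(config.flies_per_lane * (1.0 + pi) / 2.0))
                n_plus = int(np.clip(n_plus, 0, config.flies_per_lane))
                rows.append(
                    {
                        "genotype": genotype,
                        "temperature": temperature,
                        "pair": pair,
                        "reciprocal_id": reciprocal_id,
                        "n_csplus_side": n_plus,
                        "n_csminus_side": config.flies_per_lane - n_plus,
                    }
                )
    return pd.DataFrame(rows)
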