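"""Configuration dataclasses for the generator, decoder and behavior modules.

All configs are plain dataclasses with ``from_dict``/``to_dict`` round-trips
so they can be loaded from YAML/JSON and echoed into output manifests.
Validation raises :class:`ConfigError` with the offending field named.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

ODORS = ("MCH", "OCT3", "OCT1")
MBON_TYPES = ("g1", "g2", "g3", "g4", "g5")
PROTOCOLS = ("paired", "odor_only", "shock_only")
PHASES = ("pre", "post")
CS_ROLES = ("CSplus", "CSminus", "control_odor")


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending key."""


def default_amplitudes() -> dict[tuple[str, str], float]:
    """Mean odor-response amplitudes (peak ΔF/F₀) per (MBON type, odor).

    The table encodes the heterogeneity of kenyon-cell drive across the
    gamma-lobe compartments: γ3 responses are 4–5× those of γ1, MCH evokes
    stronger responses than 3-octanol, γ2 responds mainly to MCH, and γ5 is
    mostly silent (its sparse responsiveness is controlled separately via
    the responder probability).
    """
    return {
        ("g1", "MCH"): 1.0, ("g1", "OCT3"): 0.7, ("g1", "OCT1"): 0.8,
        ("g2", "MCH"): 0.8, ("g2", "OCT3"): 0.15, ("g2", "OCT1"): 0.3,
        ("g3", "MCH"): 4.5, ("g3", "OCT3"): 3.0, ("g3", "OCT1"): 3.5,
        ("g4", "MCH"): 1.5, ("g4", "OCT3"): 1.0, ("g4", "OCT1"): 1.2,
        ("g5", "MCH"): 0.5, ("g5", "OCT3"): 0.4, ("g5", "OCT1"): 0.45,
    }


def default_responder_probability() -> dict[str, float]:
    """Probability that a fly responds at all in a given compartment.

    γ1–γ4 respond in essentially every animal; γ5 dendrites respond in only
    ~17% of flies.
    """
    return {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 1.0, "g5": 0.17}


def default_plasticity() -> dict[tuple[str, str, str], float]:
    """Post/pre amplitude ratios per (protocol, MBON type, CS role).

    Encodes the qualitative plasticity pattern: associative training
    suppresses the CS+ response only in γ1 (ratio 0.5); γ2–γ4 show strong
    generalized adaptation to all odors after prolonged odor exposure
    (paired and odor-only protocols), with the γ4 "mock CS+" somewhat
    spared in the odor-only control; shock alone slightly potentiates the
    γ1 response to the two trained odors and produces only weak adaptation
    elsewhere.  Missing keys default to 1.0 (no change).
    """
    table: dict[tuple[str, str, str], float] = {("paired", "g1", "CSplus"): 0.5}
    for mbon in ("g2", "g3", "g4"):
        for role in CS_ROLES:
            table[("paired", mbon, role)] = 0.4
    for mbon in ("g2", "g3"):
        for role in CS_ROLES:
            table[("odor_only", mbon, role)] = 0.4
    table[("odor_only", "g4", "CSplus")] = 0.7
    table[("odor_only", "g4", "CSminus")] = 0.4
    table[("odor_only", "g4", "control_odor")] = 0.4
    table[("shock_only", "g1", "CSplus")] = 1.3
    table[("shock_only", "g1", "CSminus")] = 1.3
    for mbon in ("g2", "g3", "g4"):
        for role in CS_ROLES:
            table[("shock_only", mbon, role)] = 0.85
    return table


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GeneratorConfig:
    """Settings of the synthetic imaging-experiment generator.

    Parameters
    ----------
    n_flies_per_group
        Animals imaged per (protocol, MBON type) cohort.
    frame_rate
        Acquisition rate in Hz.
    odor_duration, baseline_duration, trace_duration, onset_time
        Stimulus and recording timings in seconds.  The baseline window is
        the ``baseline_duration`` preceding odor onset.
    amplitudes
        Mean response amplitude (peak ΔF/F₀) per (MBON type, odor).
    responder_probability
        Per-MBON probability that a given fly responds at all; drawn once
        per fly × odor and shared between phases.
    fly_effect_sd
        SD (log scale) of the multiplicative lognormal per-fly × odor
        amplitude factor, shared between pre and post phases.
    trial_noise_sd
        SD of additive Gaussian noise on raw fluorescence (a.u.).
    baseline_F
        Resting fluorescence level (a.u.).
    kernel_rise_tau, kernel_decay_tau
        Time constants (s) of the difference-of-exponentials response
        kernel emulating postsynaptically targeted GCaMP transients.
    plasticity
        Post/pre amplitude ratio per (protocol, MBON type, CS role);
        missing keys mean no change.
    plasticity_jitter_sd
        SD (log scale) of a lognormal session-to-session factor applied to
        every post-phase amplitude, emulating test–retest variability of
        the training effect.
    cs_counterbalance
        Alternate the CS+ odor between MCH and 3-octanol across flies.
    """

    n_flies_per_group: int = 10
    frame_rate: float = 4.0
    odor_duration: float = 2.5
    baseline_duration: float = 2.0
    trace_duration: float = 15.0
    onset_time: float = 5.0
    odors: tuple[str, ...] = ODORS
    mbon_types: tuple[str, ...] = MBON_TYPES
    protocols: tuple[str, ...] = PROTOCOLS
    amplitudes: dict[tuple[str, str], float] = field(default_factory=default_amplitudes)
    responder_probability: dict[str, float] = field(
        default_factory=default_responder_probability
    )
    fly_effect_sd: float = 0.4
    trial_noise_sd: float = 2.0
    baseline_F: float = 100.0
    kernel_rise_tau: float = 0.2
    kernel_decay_tau: float = 1.5
    plasticity: dict[tuple[str, str, str], float] = field(
        default_factory=default_plasticity
    )
    plasticity_jitter_sd: float = 0.25
    cs_counterbalance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.odors = tuple(self.odors)
        self.mbon_types = tuple(self.mbon_types)
        self.protocols = tuple(self.protocols)
        self.validate()

    def validate(self) -> None:
        for name in (
            "frame_rate", "odor_duration", "baseline_duration",
            "trace_duration", "onset_time", "baseline_F",
            "kernel_rise_tau", "kernel_decay_tau",
        ):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, f"{name} must be finite and > 0")
        for name in ("fly_effect_sd", "trial_noise_sd", "plasticity_jitter_sd"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0")
        _require(self.n_flies_per_group >= 1, "n_flies_per_group must be >= 1")
        _require(len(self.odors) > 0, "odors must be non-empty")
        _require(len(self.mbon_types) > 0, "mbon_types must be non-empty")
        _require(len(self.protocols) > 0, "protocols must be non-empty")
        _require(
            self.kernel_decay_tau != self.kernel_rise_tau,
            "kernel_decay_tau must differ from kernel_rise_tau",
        )
        period = 1.0 / self.frame_rate
        for name in ("odor_duration", "baseline_duration"):
            ratio = getattr(self, name) / period
            _require(
                abs(ratio - round(ratio)) < 1e-9,
                f"{name} must be an integer multiple of the frame period",
            )
        for key, p in self.responder_probability.items():
            _require(0.0 <= p <= 1.0, f"responder_probability[{key}] must be in [0, 1]")
        for key, a in self.amplitudes.items():
            _require(math.isfinite(a) and a >= 0, f"amplitudes[{key}] must be >= 0")
        for key, m in self.plasticity.items():
            _require(math.isfinite(m) and m >= 0, f"plasticity[{key}] must be >= 0")
        _require(
            self.onset_time - self.baseline_duration >= -1e-9,
            "onset_time must leave a full baseline window before odor onset",
        )
        _require(
            self.trace_duration - self.onset_time >= 5.0 - 1e-9,
            "trace must extend >= 5 s past odor onset",
        )

    @property
    def trained_odors(self) -> tuple[str, str]:
        """The two odors used as CS+/CS− (the first two in ``odors``)."""
        if len(self.odors) < 2:
            raise ConfigError("need at least two odors for CS assignment")
        return self.odors[0], self.odors[1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["amplitudes"] = {f"{m}:{o}": v for (m, o), v in self.amplitudes.items()}
        d["plasticity"] = {
            f"{p}:{m}:{r}": v for (p, m, r), v in self.plasticity.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        kwargs = dict(data)
        _check_keys(cls, kwargs, "generator")
        if "amplitudes" in kwargs and kwargs["amplitudes"] is not None:
            kwargs["amplitudes"] = {
                tuple(k.split(":")): float(v)
                for k, v in dict(kwargs["amplitudes"]).items()
            }
        if "plasticity" in kwargs and kwargs["plasticity"] is not None:
            kwargs["plasticity"] = {
                tuple(k.split(":")): float(v)
                for k, v in dict(kwargs["plasticity"]).items()
            }
        return cls(**kwargs)


def default_behavior_groups() -> tuple[tuple[str, str], ...]:
    """One shibire(ts) blocking line per gamma-lobe MBON, each tested at the
    permissive and the restrictive temperature."""
    return tuple(
        (f"{m}-shi", temp) for m in MBON_TYPES for temp in ("permissive", "restrictive")
    )


@dataclass
class BehaviorConfig:
    """Settings of the synthetic choice-assay cohort generator.

    ``n_lanes_per_group`` counts reciprocal lane *pairs*: each learning
    index is derived from two lanes trained with swapped CS+/CS− odor
    identities, so a group contributes ``n_lanes_per_group`` learning
    indices.  Groups listed in ``blocked_groups`` (synaptic output blocked
    during training and test) have mean learning index 0; all others have
    mean ``mean_LI_learning``.
    """

    n_lanes_per_group: int = 8
    flies_per_lane: int = 30
    mean_LI_learning: float = -0.3
    LI_sd: float = 0.1
    odor_bias: float = 0.0
    groups: tuple[tuple[str, str], ...] = field(default_factory=default_behavior_groups)
    blocked_groups: frozenset[tuple[str, str]] = field(
        default_factory=lambda: frozenset(
            {("g1-shi", "restrictive"), ("g5-shi", "restrictive")}
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(tuple(g) for g in self.groups)
        self.blocked_groups = frozenset(tuple(g) for g in self.blocked_groups)
        self.validate()

    def validate(self) -> None:
        _require(self.n_lanes_per_group >= 1, "n_lanes_per_group must be >= 1")
        _require(self.flies_per_lane >= 1, "flies_per_lane must be >= 1")
        _require(
            -1.0 <= self.mean_LI_learning <= 1.0,
            "mean_LI_learning must be in [-1, 1]",
        )
        _require(self.LI_sd >= 0, "LI_sd must be >= 0")
        _require(len(self.groups) >= 1, "groups must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        d["blocked_groups"] = sorted(list(g) for g in self.blocked_groups)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "BehaviorConfig":
        kwargs = dict(data)
        _check_keys(cls, kwargs, "behavior")
        return cls(**kwargs)


@dataclass
class DecodingConfig:
    """Settings of the pseudo-population decoding procedure.

    Defaults follow the published procedure: 1000 bootstrap drawings with
    replacement per model, 100 independent models, a linear-kernel SVM with
    C = 1 and per-feature z-standardization fitted on the training set.
    """

    n_bootstrap_draws: int = 1000
    n_models: int = 100
    included_mbons: tuple[str, ...] = MBON_TYPES
    kernel: str = "linear"
    C: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.included_mbons = tuple(self.included_mbons)
        self.validate()

    def validate(self) -> None:
        _require(self.n_bootstrap_draws >= 1, "n_bootstrap_draws must be >= 1")
        _require(self.n_models >= 1, "n_models must be >= 1")
        _require(len(self.included_mbons) >= 1, "included_mbons must be non-empty")
        _require(self.C > 0, "C must be > 0")
        _require(self.kernel in ("linear", "rbf"), "kernel must be 'linear' or 'rbf'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "DecodingConfig":
        kwargs = dict(data)
        _check_keys(cls, kwargs, "decoding")
        return cls(**kwargs)


@dataclass
class RunConfig:
    """Top-level pipeline configuration (generator + decoding + behavior)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "decoding": self.decoding.to_dict(),
            "behavior": self.behavior.to_dict(),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        _check_keys(cls, kwargs, "run")
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig.from_dict(kwargs["generator"])
        if "decoding" in kwargs:
            kwargs["decoding"] = DecodingConfig.from_dict(kwargs["decoding"])
        if "behavior" in kwargs:
            kwargs["behavior"] = BehaviorConfig.from_dict(kwargs["behavior"])
        return cls(**kwargs)


def _check_keys(cls, kwargs: dict, section: str) -> None:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section} config: {', '.join(sorted(unknown))}"
        )
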