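"""Pseudo-population decoding of CS+ vs CS− from per-animal MBON responses.

Because each animal is imaged in only one MBON type, population response
vectors are assembled across animals ("pseudo-populations"): one animal
sample per MBON type yields a feature vector of normalized response AUCs,
one for the CS+ and one for the CS− presentation.

A single model is trained and tested as follows:

1. draw one sample per MBON type at random — its CS+ and CS− vectors form
   the two-element test set; the remaining samples form the training pool;
2. draw, with replacement, ``n_bootstrap_draws`` pseudo-populations from
   the pool; each draw yields one CS+ and one CS− training vector
   (2 × n_draws vectors in total);
3. fit a support-vector machine on the training vectors (features
   z-standardized with training-set statistics) and classify the two test
   vectors; the single-model accuracy is 0, 50 or 100%.

This is repeated for ``n_models`` independent models; the mean accuracy is
compared against the 50% chance level with a one-sample Wilcoxon
signed-rank test over the per-model accuracies.  Chance-level controls
(pre-training labels, random A/B relabeling of the two trained odors) and
leave-one-MBON-out ablation reuse the identical procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from mbondecode.config import MBON_TYPES, DecodingConfig
from mbondecode.plasticity import wilcoxon_signed_rank

logger = logging.getLogger(__name__)

CONTROL_MODES = ("pretraining", "odor_only", "shock_only")


class DecodingError(ValueError):
    """Raised when the sample collection cannot support the procedure."""


@dataclass(frozen=True)
class AnimalSample:
    """One animal's pair of normalized response AUCs for one MBON type.

    For the trained condition the two values are the CS+ and CS− response;
    for the random-relabel controls they are class A and class B.
    """

    fly_id: str
    mbon_type: str
    auc_csplus: float
    auc_csminus: float
    phase: str
    protocol: str


@dataclass(frozen=True)
class DecodingResult:
    """Outcome of one decoding configuration.

    ``per_model_accuracy`` holds one value in {0, 50, 100} per model;
    ``chance_test_z``/``chance_test_p`` come from a one-sample signed-rank
    test of the per-model accuracies against the 50% chance level.
    """

    per_model_accuracy: tuple[int, ...]
    mean_accuracy: float
    chance_test_z: float
    chance_test_p: float
    config: DecodingConfig

    @property
    def n_models(self) -> int:
        return len(self.per_model_accuracy)


def build_animal_samples(
    aucs: pd.DataFrame,
    phase: str,
    protocol: str,
    value_col: str = "normalized_auc",
) -> list[AnimalSample]:
    """Assemble per-animal samples from a normalized AUC table.

    One sample per fly × MBON type, pairing the fly's CS+ and CS−
    responses in the requested phase and protocol.  Flies lacking either
    role are excluded with a logged count; an MBON type with no usable
    sample at all raises :class:`DecodingError` (the pseudo-population
    cannot be formed).  Non-responder animals are included — their
    near-zero features are data, not missingness.
    """
    sub = aucs[
        (aucs["phase"] == phase)
        & (aucs["protocol"] == protocol)
        & (aucs["cs_role"].isin(["CSplus", "CSminus"]))
    ].dropna(subset=[value_col])
    wide = sub.pivot_table(
        index=["mbon_type", "fly_id"], columns="cs_role", values=value_col,
        aggfunc="mean",
    )
    for role in ("CSplus", "CSminus"):
        if role not in wide.columns:
            wide[role] = np.nan
    complete = wide.dropna(subset=["CSplus", "CSminus"])
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning("%d fly(ies) missing a CS role excluded", n_dropped)
    samples = [
        AnimalSample(
            fly_id=str(fly), mbon_type=str(mbon),
            auc_csplus=float(row["CSplus"]), auc_csminus=float(row["CSminus"]),
            phase=phase, protocol=protocol,
        )
        for (mbon, fly), row in complete.iterrows()
    ]
    present = {s.mbon_type for s in samples}
    missing = [m for m in aucs["mbon_type"].unique() if m not in present]
    if missing:
        raise DecodingError(
            f"no usable samples for MBON type(s) {missing}; "
            "pseudo-population impossible"
        )
    return samples


def _group_by_type(
    samples: Iterable[AnimalSample], included_mbons: Sequence[str]
) -> dict[str, list[AnimalSample]]:
    groups: dict[str, list[AnimalSample]] = {m: [] for m in included_mbons}
    for s in samples:
        if s.mbon_type in groups:
            groups[s.mbon_type].append(s)
    empty = [m for m, g in groups.items() if not g]
    if empty:
        raise DecodingError(f"no samples for included MBON type(s) {empty}")
    return groups


def _canonical_order(included_mbons: Sequence[str]) -> tuple[str, ...]:
    known = [m for m in MBON_TYPES if m in included_mbons]
    extra = sorted(m for m in included_mbons if m not in MBON_TYPES)
    return tuple(known + extra)


def draw_test_split(
    samples: Sequence[AnimalSample],
    rng: np.random.Generator,
    included_mbons: Sequence[str] = MBON_TYPES,
) -> tuple[tuple[np.ndarray, np.ndarray], list[AnimalSample]]:
    """Hold out one random sample per MBON type as the test set.

    Returns ``((test_csplus, test_csminus), pool)`` where the two test
    vectors hold one AUC per included MBON type in canonical order and the
    pool is every remaining sample.
    """
    order = _canonical_order(included_mbons)
    groups = _group_by_type(samples, order)
    short = [m for m in order if len(groups[m]) < 2]
    if short:
        raise DecodingError(
            f"need >= 2 samples per MBON type to split; short: {short}"
        )
    test_plus = np.empty(len(order))
    test_minus = np.empty(len(order))
    pool: list[AnimalSample] = []
    for j, mbon in enumerate(order):
        g = groups[mbon]
        k = int(rng.integers(len(g)))
        test_plus[j] = g[k].auc_csplus
        test_minus[j] = g[k].auc_csminus
        pool.extend(s for i, s in enumerate(g) if i != k)
    return (test_plus, test_minus), pool


def bootstrap_training_vectors(
    pool: Sequence[AnimalSample],
    n_draws: int,
    rng: np.random.Generator,
    included_mbons: Sequence[str] = MBON_TYPES,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pseudo-population training vectors with replacement.

    Each of the ``n_draws`` drawings independently picks one pool sample
    per MBON type and emits one CS+ and one CS− feature vector, giving
    ``2 * n_draws`` vectors in total.

    Returns
    -------
    X : ndarray of shape (2 * n_draws, n_types)
    y : ndarray of shape (2 * n_draws,) with labels +1 (CS+) and -1 (CS−)
    """
    order = _canonical_order(included_mbons)
    groups = _group_by_type(pool, order)
    n_types = len(order)
    X_plus = np.empty((n_draws, n_types))
    X_minus = np.empty((n_draws, n_types))
    for j, mbon in enumerate(order):
        g = groups[mbon]
        plus = np.array([s.auc_csplus for s in g])
        minus = np.array([s.auc_csminus for s in g])
        idx = rng.integers(len(g), size=n_draws)
        X_plus[:, j] = plus[idx]
        X_minus[:, j] = minus[idx]
    X = np.vstack([X_plus, X_minus])
    y = np.concatenate([np.ones(n_draws, dtype=int), -np.ones(n_draws, dtype=int)])
    return X, y


def fit_predict_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    test_pair: tuple[np.ndarray, np.ndarray],
    *,
    kernel: str = "linear",
    C: float = 1.0,
    standardize: bool = True,
) -> int:
    """Fit one SVM and score the held-out CS+/CS− pair.

    Features are z-standardized with training-set statistics (the test
    vectors are transformed with the same parameters — no leakage).  The
    single-model accuracy is 50 × (number of the two test vectors
    classified correctly), i.e. 0, 50 or 100.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise DecodingError("training set contains a single class")
    X_train = np.asarray(X_train, dtype=float)
    test_plus, test_minus = test_pair
    X_test = np.vstack([test_plus, test_minus]).astype(float)
    if standardize:
        mean = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd < 1e-12] = 1.0
        X_train = (X_train - mean) / sd
        X_test = (X_test - mean) / sd
    clf = SVC(kernel=kernel, C=C)
    clf.fit(X_train, y_train)
    pred = clf.predict(X_test)
    n_correct = int(pred[0] == 1) + int(pred[1] == -1)
    return 50 * n_correct


def run_decoding(
    samples: Sequence[AnimalSample],
    config: DecodingConfig,
) -> DecodingResult:
    """Run the full repeated-model decoding procedure.

    Each of the ``n_models`` models receives an independent random stream
    spawned from the master seed (so increasing ``n_models`` extends the
    sequence without perturbing earlier models), draws its own test split
    and bootstrap training set, and contributes one accuracy in
    {0, 50, 100}.  The per-model accuracies are tested against the 50%
    chance level with a one-sample signed-rank test.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_models)
    accuracies = []
    for child in streams:
        rng = np.random.default_rng(child)
        test_pair, pool = draw_test_split(samples, rng, config.included_mbons)
        X, y = bootstrap_training_vectors(
            pool, config.n_bootstrap_draws, rng, config.included_mbons
        )
        accuracies.append(
            fit_predict_model(
                X, y, test_pair,
                kernel=config.kernel, C=config.C, standardize=config.standardize,
            )
        )
    acc = np.array(accuracies, dtype=float)
    chance = wilcoxon_signed_rank(np.full(acc.size, 50.0), acc)
    return DecodingResult(
        per_model_accuracy=tuple(int(a) for a in accuracies),
        mean_accuracy=float(acc.mean()),
        chance_test_z=chance.z,
        chance_test_p=chance.p,
        config=config,
    )


def relabel_control(
    samples: Sequence[AnimalSample],
    mode: str,
    rng: np.random.Generator | None = None,
) -> list[AnimalSample]:
    """Produce the sample collection for one chance-level control.

    ``pretraining``
        Pre-phase responses keep the CS+/CS− labels the animal was
        assigned for its *later* training; samples must come from the pre
        phase (the labeling itself happens when the samples are built, so
        this mode validates and passes through).
    ``odor_only`` / ``shock_only``
        Post-phase responses from the matching control protocol; each
        animal's two odor responses are randomly reassigned to classes A
        and B (a fair coin decides whether the pair is swapped).
    """
    samples = list(samples)
    if mode not in CONTROL_MODES:
        raise ValueError(f"unknown control mode {mode!r}")
    if mode == "pretraining":
        bad = [s for s in samples if s.phase != "pre"]
        if bad:
            raise DecodingError("pretraining control requires pre-phase samples")
        return samples
    bad = [s for s in samples if s.protocol != mode or s.phase != "post"]
    if bad:
        raise DecodingError(
            f"{mode} control requires post-phase samples from the {mode} protocol"
        )
    if rng is None:
        raise ValueError("random A/B relabeling requires an rng")
    out = []
    for s in samples:
        if rng.random() < 0.5:
            s = replace(s, auc_csplus=s.auc_csminus, auc_csminus=s.auc_csplus)
        out.append(s)
    return out


def ablate_and_decode(
    samples: Sequence[AnimalSample],
    config: DecodingConfig,
) -> dict[str, DecodingResult]:
    """Leave-one-MBON-out importance analysis.

    Repeats the full decoding procedure once per included MBON type with
    that type removed from the feature space (4-dimensional vectors for
    the default 5-type population).  All runs reuse the same master seed,
    so results are deterministic and differences across ablations reflect
    the feature spaces, not the random streams.
    """
    if len(config.included_mbons) - 1 < 2:
        raise DecodingError("ablation needs >= 2 MBON types remaining")
    results: dict[str, DecodingResult] = {}
    for excluded in config.included_mbons:
        kept = tuple(m for m in config.included_mbons if m != excluded)
        sub_config = replace(config, included_mbons=kept)
        results[excluded] = run_decoding(samples, sub_config)
    return results


def summarize_results(results: Mapping[str, DecodingResult]) -> pd.DataFrame:
    """Flatten named decoding results into a summary table."""
    rows = [
        {
            "condition": name,
            "n_models": res.n_models,
            "mean_accuracy": res.mean_accuracy,
            "chance_test_z": res.chance_test_z,
            "chance_test_p": res.chance_test_p,
            "n_features": len(res.config.included_mbons),
        }
        for name, res in results.items()
    ]
    return pd.DataFrame(rows)
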