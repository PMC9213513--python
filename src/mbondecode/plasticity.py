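"""Paired pre/post plasticity statistics.

The workhorse is a two-sided Wilcoxon signed-rank test implemented with
the reporting conventions used throughout the analysis: zero differences
are dropped, tied absolute differences are mid-ranked, the standardized
statistic z uses the tie-corrected normal approximation, and the p-value
is exact (full enumeration of the 2^n sign assignments) whenever the
effective sample size is small enough to enumerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

#: largest effective n for which the exact null distribution is enumerated
EXACT_MAX_N = 15


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome.

    ``z`` is positive when post > pre (W+ above its null mean); ``exact``
    records whether ``p`` came from enumeration or the normal
    approximation.  ``degenerate`` is set when every paired difference is
    zero, in which case z = 0 and p = 1.
    """

    n: int
    w_plus: float
    z: float
    p: float
    exact: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PairedTestResult:
    """One stratum's paired pre/post comparison."""

    mbon_type: str
    protocol: str
    cs_role: str
    n: int
    z: float
    p: float
    direction: str  # increase / decrease / none


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    exact_max_n: int = EXACT_MAX_N,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences are ``post − pre``; zero differences are dropped, ties in
    the absolute differences receive mid-ranks.  For effective n <=
    ``exact_max_n`` the two-sided p-value is computed by enumerating all
    sign assignments of the observed ranks (doubling the smaller tail,
    capped at 1); otherwise the tie-corrected normal approximation is
    used.  The standardized statistic z is always reported from the normal
    approximation, signed so that z > 0 indicates post > pre.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D sequences of equal length")
    if pre.size < 2:
        raise ValueError("need at least two pairs")
    d = post - pre
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        return WilcoxonResult(n=0, w_plus=0.0, z=0.0, p=1.0, exact=True,
                              degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)
    if n <= exact_max_n:
        dist = _exact_wplus_distribution(ranks)
        p_le = float((dist <= w_plus + 1e-9).mean())
        p_ge = float((dist >= w_plus - 1e-9).mean())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        exact = True
    else:
        p = float(2.0 * norm.sf(abs(z)))
        exact = False
    return WilcoxonResult(n=n, w_plus=w_plus, z=float(z), p=p, exact=exact)


def _exact_wplus_distribution(ranks: np.ndarray) -> np.ndarray:
    """All 2^n values of W+ over sign assignments of the given ranks."""
    n = ranks.size
    codes = np.arange(2**n, dtype=np.uint32)
    signs = (codes[:, None] >> np.arange(n)) & 1  # 0/1 matrix
    return signs @ ranks


def _direction(diffs: np.ndarray) -> str:
    med = float(np.median(diffs))
    if med > 0:
        return "increase"
    if med < 0:
        return "decrease"
    return "none"


def pre_post_comparison(
    aucs: pd.DataFrame,
    stratify_by: Sequence[str] = ("mbon_type", "protocol", "cs_role"),
    value_col: str = "auc",
) -> pd.DataFrame:
    """Paired pre-vs-post signed-rank test per stratum.

    Pairs are matched by ``fly_id`` within each stratum; flies missing
    either phase are excluded (their count is logged).  Strata with fewer
    than two complete pairs are skipped with a warning.  Returns one row
    per tested stratum with n, z, p and the direction of the median paired
    difference.
    """
    results = []
    for key, sub in aucs.dropna(subset=[value_col]).groupby(
        list(stratify_by), sort=False
    ):
        wide = sub.pivot_table(
            index="fly_id", columns="phase", values=value_col, aggfunc="mean"
        )
        if "pre" not in wide.columns or "post" not in wide.columns:
            logger.warning("stratum %s lacks a phase entirely; skipped", key)
            continue
        complete = wide.dropna(subset=["pre", "post"])
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.warning(
                "stratum %s: %d fly(ies) missing a phase excluded", key, n_dropped
            )
        if len(complete) < 2:
            logger.warning(
                "stratum %s has < 2 complete pre/post pairs; skipped", key
            )
            continue
        res = wilcoxon_signed_rank(complete["pre"].to_numpy(),
                                   complete["post"].to_numpy())
        diffs = complete["post"].to_numpy() - complete["pre"].to_numpy()
        row = dict(zip(stratify_by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=len(complete), z=res.z, p=res.p,
            direction="none" if res.degenerate else _direction(diffs),
        )
        results.append(row)
    return pd.DataFrame(results)


def pooled_us_only_test(
    aucs: pd.DataFrame,
    mbon_type: str = "g1",
    protocol: str = "shock_only",
    odors: Sequence[str] = ("MCH", "OCT3"),
    per_fly_mean: bool = False,
    value_col: str = "auc",
) -> PairedTestResult:
    """Signed-rank test pooling both trained odors in the shock-only group.

    Per-odor tests at ~10 animals are underpowered for the modest
    potentiation that shock alone induces in the γ1 MBON; pooling the two
    trained odors doubles the number of paired differences.  By default
    each fly contributes two pairs (one per odor); with
    ``per_fly_mean=True`` the two odors are averaged within fly first, so
    each fly contributes a single pair.
    """
    sub = aucs[
        (aucs["mbon_type"] == mbon_type)
        & (aucs["protocol"] == protocol)
        & (aucs["odor"].isin(list(odors)))
    ].dropna(subset=[value_col])
    if sub.empty:
        raise ValueError(
            f"no AUCs for {mbon_type}/{protocol} with odors {tuple(odors)}"
        )
    wide = sub.pivot_table(
        index=["fly_id", "odor"], columns="phase", values=value_col, aggfunc="mean"
    ).dropna(subset=["pre", "post"])
    if per_fly_mean:
        wide = wide.groupby(level="fly_id").mean()
    res = wilcoxon_signed_rank(wide["pre"].to_numpy(), wide["post"].to_numpy())
    diffs = wide["post"].to_numpy() - wide["pre"].to_numpy()
    return PairedTestResult(
        mbon_type=mbon_type, protocol=protocol, cs_role="pooled_trained_odors",
        n=len(wide), z=res.z, p=res.p,
        direction="none" if res.degenerate else _direction(diffs),
    )
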