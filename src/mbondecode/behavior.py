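"""Choice-assay preference/learning indices and group statistics.

A lane of ~30 flies distributes between a CS+ and a CS− side; its
preference index is PI = (N_CS+ − N_CS−) / (N_CS+ + N_CS−).  Two lanes
trained reciprocally (CS+/CS− odor identities swapped) are averaged into
one learning index, LI = (PI_A + PI_B) / 2, canceling innate odor bias.
Group comparisons use a one-way ANOVA with Tukey post-hoc tests plus
Bonferroni-corrected one-sample t-tests of each group's LIs against 0.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUP_COLS = ("genotype", "temperature")


def preference_index(n_csplus_side: int, n_csminus_side: int) -> float:
    """(N_CS+ − N_CS−) / total for one lane."""
    total = n_csplus_side + n_csminus_side
    if total <= 0:
        raise ValueError("preference index undefined for an empty lane")
    if n_csplus_side < 0 or n_csminus_side < 0:
        raise ValueError("fly counts must be non-negative")
    return (n_csplus_side - n_csminus_side) / total


def learning_index(pi_reciprocal_a: float, pi_reciprocal_b: float) -> float:
    """Mean of the two reciprocally trained lanes' preference indices."""
    for pi in (pi_reciprocal_a, pi_reciprocal_b):
        if not -1.0 <= pi <= 1.0:
            raise ValueError("preference indices must lie in [-1, 1]")
    return (pi_reciprocal_a + pi_reciprocal_b) / 2.0


def lane_indices(lanes: pd.DataFrame) -> pd.DataFrame:
    """Per-pair learning indices from a lane-counts table.

    Expects columns (genotype, temperature, pair, reciprocal_id,
    n_csplus_side, n_csminus_side) with reciprocal_id in {A, B}.  Returns
    one row per reciprocal pair with both PIs and the learning index.
    """
    df = lanes.copy()
    df["pi"] = [
        preference_index(int(p), int(m))
        for p, m in zip(df["n_csplus_side"], df["n_csminus_side"])
    ]
    wide = df.pivot_table(
        index=list(GROUP_COLS) + ["pair"], columns="reciprocal_id", values="pi"
    ).reset_index()
    if "A" not in wide.columns or "B" not in wide.columns:
        raise ValueError("each pair needs reciprocal lanes A and B")
    wide["learning_index"] = [
        learning_index(a, b) for a, b in zip(wide["A"], wide["B"])
    ]
    return wide.rename(columns={"A": "pi_a", "B": "pi_b"})


def behavior_group_tests(
    indices: pd.DataFrame,
    group_cols: Sequence[str] = GROUP_COLS,
    alpha: float = 0.05,
    bonferroni_divisor: int | None = None,
) -> dict:
    """Group statistics on learning indices.

    Runs a one-way ANOVA across groups, Tukey HSD pairwise comparisons,
    and a per-group two-tailed one-sample t-test of the learning indices
    against 0 at the Bonferroni-adjusted level ``alpha / divisor`` (the
    divisor defaults to the number of groups tested; real panels use
    panel-specific divisors, so it is exposed).  Degenerate groups (< 2
    indices or zero variance) are excluded with a warning.

    Returns a dict with keys ``anova`` (F, p), ``tukey`` (DataFrame of
    pairwise comparisons) and ``one_sample`` (per-group DataFrame).
    """
    groups: list[tuple] = []
    values: list[np.ndarray] = []
    for key, sub in indices.groupby(list(group_cols), sort=False):
        li = sub["learning_index"].to_numpy(dtype=float)
        if li.size < 2 or np.allclose(li.var(), 0.0):
            logger.warning("group %s degenerate (n=%d); excluded", key, li.size)
            continue
        groups.append(key if isinstance(key, tuple) else (key,))
        values.append(li)
    if len(groups) < 2:
        raise ValueError("need >= 2 non-degenerate groups")
    f_stat, anova_p = stats.f_oneway(*values)
    tukey = stats.tukey_hsd(*values)
    tukey_rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            lo, hi = tukey.confidence_interval().low[i, j], \
                tukey.confidence_interval().high[i, j]
            tukey_rows.append(
                {
                    "group_a": "/".join(map(str, groups[i])),
                    "group_b": "/".join(map(str, groups[j])),
                    "mean_diff": float(np.mean(values[i]) - np.mean(values[j])),
                    "p": float(tukey.pvalue[i, j]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    divisor = bonferroni_divisor if bonferroni_divisor is not None else len(groups)
    adj_alpha = alpha / divisor
    one_sample_rows = []
    for key, li in zip(groups, values):
        t_stat, p = stats.ttest_1samp(li, 0.0)
        one_sample_rows.append(
            {
                "group": "/".join(map(str, key)),
                "n": li.size,
                "mean_li": float(li.mean()),
                "t": float(t_stat),
                "p": float(p),
                "adjusted_alpha": adj_alpha,
                "significant": bool(p < adj_alpha),
            }
        )
    return {
        "anova": {"F": float(f_stat), "p": float(anova_p), "n_groups": len(groups)},
        "tukey": pd.DataFrame(tukey_rows),
        "one_sample": pd.DataFrame(one_sample_rows),
    }
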