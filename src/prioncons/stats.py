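"""Comparison layer: set-vs-set tests, correlations, thirds-rank consistency
and top-k ranking tables.

Tests are two-sided and uncorrected for multiple testing (raw p-values are
reported throughout).  The Mann–Whitney U test uses exact enumeration for
small samples (both n < 20, no ties) and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class DomainSummary:
    """Per-protein values feeding the comparison layer."""

    ref_id: str
    category: str  # KP | PFP | PLP
    level: str
    domain_mean_cons: float
    whole_mean_cons: float
    scps: float
    ewps_pc: float
    ewps_bs: float
    undefined: bool = False


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Welch t-test (unequal variances): (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: (U of group_a, p).

    Exact enumeration when both samples are below 20 and tie-free; otherwise
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs n >= 1")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) < 20 and len(b) < 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform).

    NaN entries (undefined-flagged values) are removed pairwise first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _third_sizes(n: int) -> tuple[int, int, int]:
    # n = 3q + r: the top third takes the first extra member, the bottom the second
    q, r = divmod(n, 3)
    return q + (1 if r >= 1 else 0), q, q + (1 if r >= 2 else 0)


def assign_thirds(values: dict[str, float]) -> dict[str, str]:
    """Rank proteins by value (descending, ties broken by id) and label
    top/middle/bottom thirds."""
    order = sorted(values, key=lambda k: (-values[k], k))
    t, m, b = _third_sizes(len(order))
    labels = {}
    for i, rid in enumerate(order):
        labels[rid] = "top" if i < t else ("middle" if i < t + m else "bottom")
    return labels


def thirds_consistency(values_by_level: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Third-of-the-ranking labels per protein per level, plus stability.

    ``values_by_level`` maps ref_id → {level → mean conservation}.  All
    proteins must cover the same levels and there must be at least 3 proteins.
    Returns a frame (ref_id, one column per level, ``stable``); the fraction
    of proteins keeping their third at every level is in
    ``df.attrs['fraction_stable']`` and the ids traversing all three thirds
    in ``df.attrs['all_three_thirds']``.
    """
    ids = sorted(values_by_level)
    if len(ids) < 3:
        raise ValueError("need at least 3 proteins")
    levels = sorted(values_by_level[ids[0]])
    for rid in ids:
        if sorted(values_by_level[rid]) != levels:
            raise ValueError(f"{rid}: levels differ from the rest")
    labels_by_level = {
        lvl: assign_thirds({rid: values_by_level[rid][lvl] for rid in ids})
        for lvl in levels
    }
    rows = []
    travellers = []
    stable_count = 0
    for rid in ids:
        labs = [labels_by_level[lvl][rid] for lvl in levels]
        stable = len(set(labs)) == 1
        stable_count += stable
        if {"top", "middle", "bottom"} <= set(labs):
            travellers.append(rid)
        rows.append({"ref_id": rid, **dict(zip(levels, labs)), "stable": stable})
    df = pd.DataFrame(rows)
    df.attrs["fraction_stable"] = stable_count / len(ids)
    df.attrs["all_three_thirds"] = travellers
    return df


RANK_KEYS = ("ewps_pc", "ewps_bs", "domain_mean_cons")


def top_k_table(summaries: list[DomainSummary], key: str, k: int) -> pd.DataFrame:
    """Top-k proteins by the given key (descending; ties by id; undefined
    entries excluded)."""
    if key not in RANK_KEYS:
        raise ValueError(f"key must be one of {RANK_KEYS}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = [s for s in summaries if not s.undefined and not np.isnan(getattr(s, key))]
    rows.sort(key=lambda s: (-getattr(s, key), s.ref_id))
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "ref_id": s.ref_id,
                "category": s.category,
                "level": s.level,
                key: getattr(s, key),
            }
            for i, s in enumerate(rows[:k])
        ]
    )


def pairwise_test_matrix(groups: dict[str, list[float]], test: str = "welch") -> pd.DataFrame:
    """All pairwise set-vs-set tests (upper-triangle style table).

    ``test`` is ``welch`` (mean conservation comparisons) or ``mwu``
    (EWPS comparisons)."""
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if test == "welch":
                t, df, p = welch_t(groups[a], groups[b])
                rows.append({"set_a": a, "set_b": b, "stat": t, "df": df, "p": p})
            elif test == "mwu":
                u, p = mann_whitney(groups[a], groups[b])
                rows.append({"set_a": a, "set_b": b, "stat": u, "df": np.nan, "p": p})
            else:
                raise ValueError("test must be 'welch' or 'mwu'")
    return pd.DataFrame(rows)
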