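import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from prioncons.stats import (
    DomainSummary,
    assign_thirds,
    mann_whitney,
    pairwise_test_matrix,
    pearson_r,
    thirds_consistency,
    top_k_table,
    welch_t,
)


def oracle_welch(a, b):
    """Closed-form Welch statistic, df and p (textbook formulas)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def oracle_mwu_exact(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of arrangements."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)

    def u_of(idx):
        xa = [pooled[i] for i in idx]
        xb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for x in xa for y in xb if x > y) + 0.5 * sum(
            1 for x in xa for y in xb if x == y
        )

    u_obs = u_of(range(n))
    us = [u_of(c) for c in combinations(range(len(pooled)), n)]
    ge = sum(1 for u in us if u >= u_obs) / len(us)
    le = sum(1 for u in us if u <= u_obs) / len(us)
    return u_obs, min(1.0, 2 * min(ge, le))


def test_welch_identical_groups():
    t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0
    assert p == pytest.approx(1.0)


def test_welch_matches_closed_form():
    a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
    t, df, p = welch_t(a, b)
    to, dfo, po = oracle_welch(a, b)
    assert t == pytest.approx(to, abs=1e-10)
    assert df == pytest.approx(dfo, abs=1e-10)
    assert p == pytest.approx(po, abs=1e-10)


def test_welch_p_decreases_with_shift(rng):
    base = rng.normal(0, 1, size=30)
    ps = [welch_t(base, base + shift)[2] for shift in (0.5, 1.0, 2.0, 4.0)]
    assert all(b < a for a, b in zip(ps, ps[1:]))


def test_welch_requires_two_per_group():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


def test_mwu_hand_case_and_identity():
    u, p = mann_whitney([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(1 / 3, abs=1e-12)
    _, p_same = mann_whitney([1, 2, 3], [1, 2, 3])
    assert p_same == pytest.approx(1.0)


def test_mwu_matches_enumeration_oracle(rng):
    for _ in range(10):
        na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        vals = rng.permutation(100)[: na + nb].astype(float)  # tie-free
        a, b = vals[:na], vals[na:]
        u, p = mann_whitney(a, b)
        uo, po = oracle_mwu_exact(a, b)
        assert u == uo
        assert p == pytest.approx(po, abs=1e-12)


def test_mwu_exact_and_asymptotic_agree_at_n25(rng):
    a = rng.normal(0, 1, size=25)
    b = rng.normal(0.5, 1, size=25)
    _, p_asym = mann_whitney(a, b)  # n >= 20 -> normal approximation
    p_exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
    assert abs(p_asym - p_exact) < 0.01


def test_pearson_perfect_and_formula(rng):
    x = np.arange(10.0)
    r, _ = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)
    a = rng.normal(size=12)
    b = 0.3 * a + rng.normal(size=12)
    r, p = pearson_r(a, b)
    ro = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
    t = ro * math.sqrt(10 / (1 - ro**2))
    po = 2 * sps.t.sf(abs(t), 10)
    assert r == pytest.approx(ro, abs=1e-10)
    assert p == pytest.approx(po, abs=1e-10)


def test_pearson_drops_nan_pairwise():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 4.0, 6.0, 8.0, 10.0]
    r, _ = pearson_r(x, y)
    assert r == pytest.approx(1.0)


def test_thirds_identical_rankings_fully_stable():
    vals = {f"p{i}": {"genus": float(i), "class": float(2 * i)} for i in range(9)}
    df = thirds_consistency(vals)
    assert df.attrs["fraction_stable"] == 1.0


def test_thirds_reversed_ranking_keeps_only_middle():
    vals = {f"p{i}": {"a": float(i), "b": float(-i)} for i in range(9)}
    df = thirds_consistency(vals)
    assert df.attrs["fraction_stable"] == pytest.approx(1 / 3)
    stable_ids = set(df[df["stable"]]["ref_id"])
    assert stable_ids == {"p3", "p4", "p5"}  # the middle third under both orders


def test_thirds_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    vals = {f"p{i}": {"a": float(rng.normal()), "b": float(rng.normal())} for i in range(10)}
    transformed = {
        k: {lvl: math.exp(v) for lvl, v in d.items()} for k, d in vals.items()
    }
    d1 = thirds_consistency(vals)
    d2 = thirds_consistency(transformed)
    assert d1.attrs["fraction_stable"] == d2.attrs["fraction_stable"]
    assert d1.equals(d2)


def test_thirds_sizes_follow_top_first_rule():
    labels = assign_thirds({f"p{i}": float(-i) for i in range(10)})
    counts = {lab: list(labels.values()).count(lab) for lab in ("top", "middle", "bottom")}
    assert counts == {"top": 4, "middle": 3, "bottom": 3}


def _summaries(scores):
    return [
        DomainSummary(ref_id=f"p{i}", category="PLP", level="class",
                      domain_mean_cons=0.0, whole_mean_cons=0.0,
                      scps=0.0, ewps_pc=s, ewps_bs=s)
        for i, s in enumerate(scores)
    ]


def test_top_k_sorting_and_ties():
    tbl = top_k_table(_summaries([5.0, 9.0, 9.0, 1.0]), "ewps_pc", 3)
    assert tbl["ref_id"].tolist() == ["p1", "p2", "p0"]  # tie broken by id
    full = top_k_table(_summaries([5.0, 9.0]), "ewps_pc", 10)
    assert len(full) == 2
    with pytest.raises(ValueError):
        top_k_table(_summaries([1.0]), "scps", 3)


def test_top_k_excludes_undefined():
    sums = _summaries([5.0, 9.0])
    sums.append(DomainSummary(ref_id="bad", category="PLP", level="class",
                              domain_mean_cons=0.0, whole_mean_cons=0.0,
                              scps=0.0, ewps_pc=99.0, ewps_bs=99.0, undefined=True))
    tbl = top_k_table(sums, "ewps_pc", 10)
    assert "bad" not in tbl["ref_id"].tolist()


def test_pairwise_matrix_covers_all_pairs(rng):
    groups = {"KP": list(rng.normal(size=5)), "PFP": list(rng.normal(size=6)),
              "PLP": list(rng.normal(size=7))}
    df = pairwise_test_matrix(groups, "welch")
    assert len(df) == 3
    df2 = pairwise_test_matrix(groups, "mwu")
    assert set(zip(df2["set_a"], df2["set_b"])) == {("KP", "PFP"), ("KP", "PLP"), ("PFP", "PLP")}
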