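import math

import numpy as np
import pytest

from prioncons.matrices import BLOSUM62, AA_INDEX
from prioncons.pairwise import (
    AlignParams,
    DEFAULT_PARAMS,
    EncodedProteome,
    best_hits,
    bit_score,
    e_value,
    local_align,
    sw_raw_score,
    sw_scores_vs_set,
)
from prioncons.seqio import ProteinRecord

AA20 = "ARNDCQEGHILKMFPSTWYV"


def oracle_local_score(a: str, b: str, open_first: int = 12, extend: int = 1) -> int:
    """Independent brute-force Gotoh local DP (full matrices, no tricks)."""
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_first, E[i][j - 1] - extend)
            F[i][j] = max(H[i - 1][j] - open_first, F[i - 1][j] - extend)
            s = BLOSUM62[AA_INDEX[a[i - 1]], AA_INDEX[b[j - 1]]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _random_seq(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


def test_raw_score_matches_bruteforce_oracle(rng):
    for _ in range(100):
        a = _random_seq(rng, int(rng.integers(8, 13)))
        b = _random_seq(rng, int(rng.integers(8, 13)))
        assert sw_raw_score(a, b) == oracle_local_score(a, b)


def test_raw_score_is_symmetric(rng):
    for _ in range(20):
        a = _random_seq(rng, 40)
        b = _random_seq(rng, 35)
        assert sw_raw_score(a, b) == sw_raw_score(b, a)


def test_self_alignment_is_identity_and_diagonal_sum(rng):
    seq = _random_seq(rng, 30)
    rec = ProteinRecord(id="a", species="s", seq=seq)
    hit = local_align(rec, rec)
    assert hit.pct_identity == 100.0
    assert hit.raw_score == sum(BLOSUM62[AA_INDEX[c], AA_INDEX[c]] for c in seq)
    assert hit.aligned_length == len(seq)


def test_self_hit_dominance(rng):
    a = ProteinRecord(id="a", species="s", seq=_random_seq(rng, 50))
    self_bits = local_align(a, a).bitscore
    for i in range(10):
        b = ProteinRecord(id=f"b{i}", species="s", seq=_random_seq(rng, 50))
        assert local_align(a, b).bitscore <= self_bits


def test_disjoint_alphabet_pair_yields_empty_hit():
    a = ProteinRecord(id="a", species="s", seq="AAAA")
    b = ProteinRecord(id="b", species="s", seq="WWWW")
    hit = local_align(a, b)
    assert hit.raw_score == 0.0
    assert hit.pct_identity == 0.0
    assert hit.aligned_length == 0


def test_short_sequence_rejected():
    a = ProteinRecord(id="a", species="s", seq="M")
    b = ProteinRecord(id="b", species="s", seq="MNQLL")
    with pytest.raises(ValueError):
        local_align(a, b)


def test_karlin_altschul_conversions():
    p = DEFAULT_PARAMS
    s = 100.0
    assert bit_score(s, p) == pytest.approx((0.267 * s - math.log(0.041)) / math.log(2))
    assert e_value(s, 200, 300, p) == pytest.approx(0.041 * 200 * 300 * math.exp(-0.267 * s))
    # monotone: higher raw score -> higher bits, lower E
    assert bit_score(101.0, p) > bit_score(100.0, p)
    assert e_value(101.0, 200, 300, p) < e_value(100.0, 200, 300, p)


def _mutate(rng, seq, p):
    return "".join(
        (rng.choice(list(AA20)) if rng.random() < p else c) for c in seq
    )


def test_best_hits_finds_exact_copy_and_planted_ortholog(rng):
    q = ProteinRecord(id="q", species="ref", seq=_random_seq(rng, 120))
    copy = ProteinRecord(id="copy", species="o", seq=q.seq)
    planted = ProteinRecord(id="orth", species="o", seq=_mutate(rng, q.seq, 0.3))
    decoys = [ProteinRecord(id=f"d{i}", species="o", seq=_random_seq(rng, 120))
              for i in range(10)]
    hits = best_hits([q], [copy] + decoys)
    assert hits["q"].subject_id == "copy"
    hits = best_hits([q], [planted] + decoys)
    assert hits["q"].subject_id == "orth"
    assert hits["q"].pct_identity > 60


def test_best_hits_drops_queries_above_evalue_threshold(rng):
    q = ProteinRecord(id="q", species="ref", seq=_random_seq(rng, 100))
    junk = [ProteinRecord(id=f"d{i}", species="o", seq=_random_seq(rng, 100))
            for i in range(5)]
    hits = best_hits([q], junk, evalue_max=1e-30)
    assert "q" not in hits


def test_batch_scores_agree_with_single_calls(rng):
    queries = [_random_seq(rng, 60) for _ in range(5)]
    subjects = [ProteinRecord(id=f"s{i}", species="o", seq=_random_seq(rng, 70))
                for i in range(8)]
    enc = EncodedProteome(subjects)
    for qs in queries:
        q = ProteinRecord(id="q", species="r", seq=qs)
        batch = sw_scores_vs_set(q, enc)
        singles = [sw_raw_score(qs, s.seq) for s in subjects]
        assert batch.tolist() == singles
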