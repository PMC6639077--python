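import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prioncons.matrices import AA_INDEX
from prioncons.prionscore import (
    PrionScoreParams,
    default_tables,
    llr_window_scan,
    load_tables,
    score_family,
    score_sequence,
)
from prioncons.seqio import ProteinRecord

AA20 = "ARNDCQEGHILKMFPSTWYV"
HYDROPHOBIC = "AILVFMW"


def _nq_tract(rng, length, nq=0.8):
    out = []
    for _ in range(length):
        if rng.random() < nq:
            out.append("N" if rng.random() < 0.55 else "Q")
        else:
            out.append(rng.choice(list(AA20)))
    return "".join(out)


def _hydrophobic(rng, length):
    return "".join(rng.choice(list(HYDROPHOBIC), size=length))


def test_default_tables_are_valid_distributions():
    t = default_tables()
    assert t.prion_freqs[:20].sum() == pytest.approx(1.0, abs=1e-9)
    assert t.background_freqs[:20].sum() == pytest.approx(1.0, abs=1e-9)
    lo = t.log_odds
    assert lo[AA_INDEX["N"]] > 0 and lo[AA_INDEX["Q"]] > 0
    assert lo[AA_INDEX["L"]] < 0
    assert lo[AA_INDEX["X"]] == 0.0


def test_custom_tables_roundtrip_and_validation(tmp_path):
    f = tmp_path / "prion.tsv"
    lines = ["residue\tprobability"] + [f"{aa}\t0.05" for aa in AA20]
    f.write_text("\n".join(lines) + "\n")
    t = load_tables(prion_path=f)
    assert np.allclose(t.prion_freqs[:20], 0.05)
    bad = tmp_path / "bad.tsv"
    bad.write_text("residue\tprobability\nN\t1.0\n")
    with pytest.raises(ValueError, match="missing"):
        load_tables(prion_path=bad)


def test_llr_scan_matches_bruteforce(rng):
    t = default_tables()
    lo = t.log_odds
    for _ in range(20):
        seq = "".join(rng.choice(list(AA20), size=10))
        best, start = llr_window_scan(seq, t, 5)
        brute = [
            (sum(lo[AA_INDEX[c]] for c in seq[i : i + 5]), i + 1) for i in range(6)
        ]
        bbest = max(v for v, _ in brute)
        assert best == pytest.approx(bbest, abs=1e-12)
        assert start == min(i for v, i in brute if v == pytest.approx(bbest))


def test_llr_scan_edge_cases():
    t = default_tables()
    seq = "N" * 30
    val, start = llr_window_scan(seq, t, 10)
    assert start == 1  # all windows tie; smallest start wins
    full, start_full = llr_window_scan(seq, t, 30)
    assert full == pytest.approx(len(seq) * t.log_odds[AA_INDEX["N"]])
    over, _ = llr_window_scan(seq, t, 50)  # window longer than the sequence
    assert over == pytest.approx(full)


def test_all_hydrophobic_scores_exactly_zero():
    res = score_sequence("L" * 200)
    assert res.prd_score == 0.0
    assert res.domain_interval is None


def test_planted_tract_is_recovered(rng):
    for _ in range(5):
        tract = _nq_tract(rng, 80)
        seq = _hydrophobic(rng, 100) + tract + _hydrophobic(rng, 100)
        res = score_sequence(seq)
        assert res.prd_score > 0
        s, e = res.domain_interval
        inter = max(0, min(e, 180) - max(s, 101) + 1)
        union = (e - s + 1) + 80 - inter
        assert inter / union >= 0.8


def test_prd_monotone_in_tract_length(rng):
    flank = _hydrophobic(rng, 80)
    scores = [
        score_sequence(flank + "NQ" * k + flank).prd_score for k in (30, 40, 50, 60)
    ]
    assert all(b >= a for a, b in zip(scores, scores[1:]))
    assert scores[0] > 0


def test_appending_x_never_changes_score(rng):
    seq = _hydrophobic(rng, 50) + _nq_tract(rng, 80) + _hydrophobic(rng, 50)
    base = score_sequence(seq)
    padded = score_sequence(seq + "X" * 30)
    assert padded.prd_score == pytest.approx(base.prd_score, abs=1e-12)


def test_short_sequence_uses_full_window():
    t = default_tables()
    res = score_sequence("NQNQNQNQNQ")  # shorter than the 60-residue core
    assert res.llr == pytest.approx(llr_window_scan("NQNQNQNQNQ", t, 60)[0])
    assert res.prd_score == 0.0  # no prion parse can satisfy the core length


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 10**6))
def test_min_run_invariant(seed):
    """Every positive score comes with a domain of at least core length."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 300))
    # mixture of background and N/Q-rich stretches
    parts = []
    while sum(map(len, parts)) < n:
        if rng.random() < 0.4:
            parts.append(_nq_tract(rng, int(rng.integers(10, 90))))
        else:
            parts.append("".join(rng.choice(list(AA20), size=int(rng.integers(10, 90)))))
    seq = "".join(parts)[:n]
    res = score_sequence(seq)
    assert res.prd_score >= 0.0
    if res.prd_score > 0:
        s, e = res.domain_interval
        assert e - s + 1 >= 60


def test_family_scoring_matches_order_and_detects_lost_tracts(rng):
    tract = _nq_tract(rng, 80)
    with_tract = ProteinRecord(
        id="keep", species="a", seq=_hydrophobic(rng, 80) + tract + _hydrophobic(rng, 80)
    )
    without = ProteinRecord(id="lost", species="b", seq=_hydrophobic(rng, 240))
    twin = ProteinRecord(id="twin", species="c", seq=with_tract.seq)
    results = score_family([with_tract, without, twin])
    assert [r.id for r in results] == ["keep", "lost", "twin"]
    assert results[0].prd_score > 0
    assert results[1].prd_score == 0.0
    assert results[2].prd_score == results[0].prd_score
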