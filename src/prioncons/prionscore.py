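"""Prion-likeness scoring from a two-state composition HMM.

A sequence is modelled as emissions from either a background state or a
prion-like state whose residue frequencies are those of experimentally
characterized N/Q-rich yeast prion-forming domains.  Working in log-odds
units (background emissions cancel), Viterbi decoding under a minimum
prion-state run length (the core length, default 60 residues) yields the
predicted prion domain.  Scores:

* PRD score — sum of per-residue log-odds ln(prion/background) over all
  decoded prion-state residues, clamped at 0.  For the reference protein of
  a family this is the single-species prion score (SCPS).
* LLR — the maximum log-odds sum over any window of core length.

The shipped frequency tables (``data/*.tsv``) give an N/Q-rich prion-domain
composition modelled on characterized yeast prion domains and a standard
S. cerevisiae proteome background; both are approximate and swappable via
two-column TSVs (residue, probability).  X residues emit log-odds 0, so
appending unknowns never changes a score.  The single background table is
applied to every species scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .matrices import AA_INDEX, ALPHABET
from .seqio import ProteinRecord


@dataclass(frozen=True)
class FrequencyTables:
    """Prion-state and background residue frequencies (each summing to 1)."""

    prion_freqs: np.ndarray      # length 21; X entry unused
    background_freqs: np.ndarray

    def __post_init__(self):
        for name, t in (("prion", self.prion_freqs), ("background", self.background_freqs)):
            if abs(t[:20].sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies sum to {t[:20].sum()}, not 1")
            if (t[:20] <= 0).any():
                raise ValueError(f"{name} frequencies must all be positive")

    @property
    def log_odds(self) -> np.ndarray:
        lo = np.zeros(21)
        lo[:20] = np.log(self.prion_freqs[:20] / self.background_freqs[:20])
        return lo  # X stays 0


def _read_freq_tsv(path_or_buf) -> np.ndarray:
    df = pd.read_csv(path_or_buf, sep="\t")
    freqs = np.zeros(21)
    for _, row in df.iterrows():
        aa = str(row["residue"]).upper()
        if aa not in AA_INDEX or aa == "X":
            raise ValueError(f"unknown residue {aa!r} in frequency table")
        freqs[AA_INDEX[aa]] = float(row["probability"])
    missing = [a for a in ALPHABET[:20] if freqs[AA_INDEX[a]] == 0.0]
    if missing:
        raise ValueError(f"frequency table missing residues {missing}")
    freqs[:20] /= freqs[:20].sum()
    return freqs


def load_tables(prion_path=None, background_path=None) -> FrequencyTables:
    """Load frequency tables, defaulting to the shipped composition files."""
    data = resources.files("prioncons") / "data"
    prion = _read_freq_tsv(prion_path or (data / "prion_freqs.tsv"))
    bg = _read_freq_tsv(background_path or (data / "background_freqs.tsv"))
    return FrequencyTables(prion_freqs=prion, background_freqs=bg)


_DEFAULT_TABLES: FrequencyTables | None = None


def default_tables() -> FrequencyTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_tables()
    return _DEFAULT_TABLES


@dataclass(frozen=True)
class PrionScoreParams:
    core_length: int = 60
    # single enter/exit probability pair; exit = 1/core makes the expected
    # prion-state run equal the core length
    p_enter: float | None = None
    p_exit: float | None = None

    def resolved(self) -> tuple[float, float]:
        p = 1.0 / self.core_length
        return (self.p_enter if self.p_enter is not None else p,
                self.p_exit if self.p_exit is not None else p)


DEFAULT_PRION_PARAMS = PrionScoreParams()


@dataclass(frozen=True)
class PrionScoreResult:
    id: str
    prd_score: float                      # clamped at 0
    llr: float
    llr_start: int                        # 1-based window start
    domain_interval: tuple[int, int] | None  # 1-based inclusive


def llr_window_scan(seq: str, tables: FrequencyTables, window: int) -> tuple[float, int]:
    """Best log-odds sum over all windows of the given length.

    Ties break to the smallest (1-based) start.  A window longer than the
    sequence degenerates to the single full-length window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lo = tables.log_odds
    vals = lo[[AA_INDEX[c] for c in seq]]
    if window >= len(vals):
        return float(vals.sum()), 1
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    sums = csum[window:] - csum[:-window]
    best = float(sums.max())
    # ties (within float accumulation noise) break to the smallest start
    start = int(np.nonzero(sums >= best - 1e-9)[0][0])
    return float(sums[start]), start + 1


def _viterbi_decode(lo: np.ndarray, core: int, p_enter: float, p_exit: float) -> np.ndarray:
    """Viterbi path (bool prion-state per residue) under a min-run constraint.

    States: background, then a chain P_1..P_core; P_k (k < core) must advance,
    P_core may self-loop or exit, and the path may not end mid-chain — so any
    decoded prion run has length >= core.
    """
    L = len(lo)
    if L < core:
        return np.zeros(L, dtype=bool)
    t_bb = math.log1p(-p_enter)
    t_bp = math.log(p_enter)
    t_pp = math.log1p(-p_exit)
    t_pb = math.log(p_exit)
    NEG = -1e30
    n_states = core + 1  # 0 = background, k = P_k
    score = np.full(n_states, NEG)
    score[0] = 0.0
    back = np.zeros((L, n_states), dtype=np.int32)
    for i in range(L):
        new = np.full(n_states, NEG)
        # background: from background or from P_core
        s_bb = score[0] + t_bb
        s_pb = score[core] + t_pb
        if s_bb >= s_pb:
            new[0] = s_bb
            back[i, 0] = 0
        else:
            new[0] = s_pb
            back[i, 0] = core
        # P_1: only entered from background
        new[1] = score[0] + t_bp + lo[i]
        back[i, 1] = 0
        # P_k forced advance (probability 1)
        new[2 : core + 1] = score[1:core] + lo[i]
        back[i, 2 : core + 1] = np.arange(1, core)
        # P_core self-loop
        stay = score[core] + t_pp + lo[i]
        if stay > new[core]:
            new[core] = stay
            back[i, core] = core
        score = new
    # end only in background or P_core
    state = 0 if score[0] >= score[core] else core
    path = np.zeros(L, dtype=bool)
    for i in range(L - 1, -1, -1):
        path[i] = state != 0
        state = back[i, state]
    return path


def score_sequence(
    rec: ProteinRecord | str,
    tables: FrequencyTables | None = None,
    params: PrionScoreParams = DEFAULT_PRION_PARAMS,
) -> PrionScoreResult:
    """PRD score, LLR and predicted prion-domain interval for one sequence.

    Negative decoded totals clamp to 0 (and the interval is dropped), so
    sequences the model finds nothing in score exactly 0, never negative.
    """
    if isinstance(rec, str):
        rec = ProteinRecord(id="seq", species="", seq=rec)
    tables = tables or default_tables()
    lo = tables.log_odds[[AA_INDEX[c] for c in rec.seq]]
    p_enter, p_exit = params.resolved()
    path = _viterbi_decode(lo, params.core_length, p_enter, p_exit)
    unclamped = float(lo[path].sum()) if path.any() else 0.0
    interval = None
    if path.any() and unclamped > 0:
        # longest-scoring run if several
        runs = []
        start = None
        for i, p in enumerate(path):
            if p and start is None:
                start = i
            elif not p and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(path) - 1))
        best = max(runs, key=lambda r: lo[r[0] : r[1] + 1].sum())
        interval = (best[0] + 1, best[1] + 1)
    llr, llr_start = llr_window_scan(rec.seq, tables, params.core_length)
    return PrionScoreResult(
        id=rec.id,
        prd_score=max(unclamped, 0.0),
        llr=llr,
        llr_start=llr_start,
        domain_interval=interval if unclamped > 0 else None,
    )


def score_family(members: list[ProteinRecord],
                 tables: FrequencyTables | None = None,
                 params: PrionScoreParams = DEFAULT_PRION_PARAMS) -> list[PrionScoreResult]:
    """Score each family member on its ungapped sequence, in family order."""
    if not members:
        raise ValueError("empty family")
    return [score_sequence(m, tables, params) for m in members]
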