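"""The evolutionarily-weighted prion score (EWPS).

EWPS = Σ wᵢPᵢ / Σ wᵢ over a reference protein's orthologs, where Pᵢ is the
ortholog's prion propensity score (PRD score clamped at 0 — zeros are kept in
the summation) and wᵢ is one of two divergence weightings:

* PC: wᵢ = 1 − %identityᵢ/100
* BS: wᵢ = bitscoreᵢ / self-bitscore

The reference protein itself is excluded from the summation (its PC weight
would be 0 and its BS weight would dominate).  Note the two published
weightings pull in opposite directions — PC up-weights divergent orthologs
while BS up-weights similar ones; both are implemented verbatim and in
practice rank families almost identically (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .orthology import OrthologFamily

log = logging.getLogger(__name__)

SCHEMES = ("PC", "BS")


def weight_pc(pct_identity: float) -> float:
    """Percent-identity weighting: 1 − %identity/100."""
    if not (0.0 <= pct_identity <= 100.0):
        raise ValueError(f"pct_identity {pct_identity} outside [0, 100]")
    return 1.0 - pct_identity / 100.0


def weight_bs(bitscore: float, self_bitscore: float) -> float:
    """Bitscore-ratio weighting: bitscoreᵢ / self-bitscore (clamped to ≤ 1)."""
    if self_bitscore <= 0:
        raise ValueError("self_bitscore must be positive")
    if bitscore < 0:
        raise ValueError("bitscore must be non-negative")
    if bitscore > self_bitscore:
        log.warning("bitscore %.2f above self-bitscore %.2f; clamping", bitscore, self_bitscore)
        bitscore = self_bitscore
    return bitscore / self_bitscore


@dataclass(frozen=True)
class EWPSResult:
    ref_id: str
    level: str
    scheme: str
    ewps: float          # NaN when undefined
    n: int
    terms: list[tuple[str, float, float]]  # (ortholog_id, P_i, w_i)
    undefined: bool = False


def compute_ewps(family: OrthologFamily, scores: list[float], scheme: str) -> EWPSResult:
    """Weighted mean of ortholog prion scores for one family.

    ``scores`` must align one-to-one with family.orthologs.  Families with no
    orthologs, or with zero total weight (all orthologs identical under PC),
    are flagged undefined.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if len(scores) != family.n:
        raise ValueError(f"{len(scores)} scores for {family.n} orthologs")
    if family.n == 0:
        return EWPSResult(family.reference.id, family.level, scheme,
                          float("nan"), 0, [], undefined=True)
    terms = []
    for o, p in zip(family.orthologs, scores):
        w = (weight_pc(o.pct_identity) if scheme == "PC"
             else weight_bs(o.bitscore, o.self_bitscore))
        terms.append((o.record.id, float(p), float(w)))
    wsum = sum(w for _, _, w in terms)
    if wsum == 0.0:
        log.warning("family %s: total weight 0 under %s; EWPS undefined",
                    family.reference.id, scheme)
        return EWPSResult(family.reference.id, family.level, scheme,
                          float("nan"), family.n, terms, undefined=True)
    ewps = sum(w * p for _, p, w in terms) / wsum
    return EWPSResult(family.reference.id, family.level, scheme,
                      float(ewps), family.n, terms)


def compare_schemes(results_pc: list[EWPSResult], results_bs: list[EWPSResult]) -> pd.DataFrame:
    """Per-protein |EWPS_PC − EWPS_BS| plus a Spearman rank-correlation summary.

    The returned frame has one row per protein and carries the summary in
    ``df.attrs['spearman_r']`` / ``df.attrs['spearman_p']`` (undefined
    entries excluded pairwise).
    """
    pc = {r.ref_id: r for r in results_pc}
    bs = {r.ref_id: r for r in results_bs}
    if set(pc) != set(bs):
        raise ValueError("scheme result sets cover different proteins")
    rows = []
    for rid in pc:
        a, b = pc[rid], bs[rid]
        rows.append({
            "ref_id": rid,
            "ewps_pc": a.ewps,
            "ewps_bs": b.ewps,
            "abs_delta": abs(a.ewps - b.ewps),
            "undefined": a.undefined or b.undefined,
        })
    df = pd.DataFrame(rows).sort_values("ref_id").reset_index(drop=True)
    ok = df[~df["undefined"]]
    if len(ok) >= 3:
        r, p = sps.spearmanr(ok["ewps_pc"], ok["ewps_bs"])
        df.attrs["spearman_r"] = float(r)
        df.attrs["spearman_p"] = float(p)
    else:
        df.attrs["spearman_r"] = float("nan")
        df.attrs["spearman_p"] = float("nan")
    return df


def ewps_table(results: list[EWPSResult], categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Ranking-table serialization: undefined families are reported with
    EWPS 0 but keep their flag (they are excluded from correlations)."""
    rows = []
    for r in results:
        rows.append({
            "ref_id": r.ref_id,
            "category": (categories or {}).get(r.ref_id),
            "level": r.level,
            "scheme": r.scheme,
            "ewps": 0.0 if r.undefined else r.ewps,
            "n": r.n,
            "flag": "undefined" if r.undefined else "",
        })
    return pd.DataFrame(rows)
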