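"""Entropy-based per-column conservation with cross-column normalization.

For alignment column i with residue frequencies p_ia (unweighted counts over
non-gap, non-X symbols), the raw score is S(i) = Σ_a p_ia ln p_ia, so a fully
conserved column scores 0 and diversity drives the score negative.  Columns
whose gap fraction exceeds a threshold (default 0.5) are masked.  Raw scores
over the unmasked columns are normalized to zero mean and unit SD, so that a
positive normalized value means more conserved than the alignment average.
Per-domain summaries are means/SDs of the normalized scores over the
alignment columns onto which the domain maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrices import AA_INDEX
from .seqio import AlignmentBlock

log = logging.getLogger(__name__)

_X = AA_INDEX["X"]


@dataclass
class ConservationProfile:
    column_scores: np.ndarray  # normalized; NaN on masked columns
    raw_scores: np.ndarray
    n_rows: int
    masked_columns: np.ndarray  # boolean mask, True = masked

    @property
    def ncols(self) -> int:
        return len(self.column_scores)


def column_conservation(block: AlignmentBlock, gap_mask_threshold: float = 0.5) -> ConservationProfile:
    """Score every column of an alignment (needs ≥ 2 rows).

    Gaps (and X) are excluded from the frequency counts rather than treated
    as a 21st symbol.  If all unmasked raw scores are identical the
    normalized scores are all zero (with a warning).
    """
    if block.nrows < 2:
        raise ValueError("alignment must have at least 2 rows")
    n, m = block.nrows, block.ncols
    counts = np.zeros((m, 21))
    gap_counts = np.zeros(m)
    for _, row in block.rows:
        for c, ch in enumerate(row):
            if ch == "-":
                gap_counts[c] += 1
            else:
                counts[c, AA_INDEX[ch]] += 1
    counts[:, _X] = 0.0  # unknown residues carry no compositional information
    totals = counts.sum(axis=1)
    raw = np.zeros(m)
    for c in range(m):
        if totals[c] > 0:
            p = counts[c, counts[c] > 0] / totals[c]
            raw[c] = float((p * np.log(p)).sum())
    masked = (gap_counts / n) > gap_mask_threshold
    masked |= totals == 0
    unmasked_raw = raw[~masked]
    if unmasked_raw.size == 0:
        raise ValueError("all columns masked")
    mu = unmasked_raw.mean()
    sd = unmasked_raw.std()
    scores = np.full(m, np.nan)
    if sd < 1e-12:
        log.warning("zero variance across columns; normalized scores set to 0")
        scores[~masked] = 0.0
    else:
        scores[~masked] = (raw[~masked] - mu) / sd
    return ConservationProfile(column_scores=scores, raw_scores=raw,
                               n_rows=n, masked_columns=masked)


def domain_mean_conservation(profile: ConservationProfile,
                             domain_columns: np.ndarray) -> tuple[float, float]:
    """Mean and SD of normalized conservation over unmasked domain columns.

    ``domain_columns`` are 1-based alignment column indices (as produced by
    msa.map_domain_to_columns).  Returns (nan, nan) when every domain column
    is masked; callers exclude such domains from downstream statistics.
    """
    cols = np.asarray(domain_columns, dtype=int) - 1
    if cols.size and (cols.min() < 0 or cols.max() >= profile.ncols):
        raise ValueError("domain columns outside profile")
    vals = profile.column_scores[cols]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        log.warning("all domain columns masked; mean conservation undefined")
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.std())


def whole_mean_conservation(profile: ConservationProfile) -> tuple[float, float]:
    """Mean and SD of normalized conservation over all unmasked columns.

    The mean is 0 and SD 1 by construction; kept as an explicit summary so
    output tables carry the same fields for domains and whole sequences.
    """
    vals = profile.column_scores[~profile.masked_columns]
    return float(vals.mean()), float(vals.std())
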