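"""Progressive multiple alignment for ortholog families.

Desk-scale stand-in for an external aligner: UPGMA guide tree on pairwise
identity distances (d = 1 − %identity/100), then profile–profile global
Needleman–Wunsch/Gotoh merges under BLOSUM62 with affine gaps (same gap
convention as the pairwise module).  Precomputed external alignments can be
ingested instead via seqio.read_aligned_fasta.

Profile columns are occupancy-weighted frequency vectors (counts divided by
the number of rows, gaps contributing zero), so sparsely occupied columns
carry proportionally less substitution score.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .matrices import AA_INDEX, ALPHABET, BLOSUM62
from .orthology import OrthologFamily
from .pairwise import AlignParams, DEFAULT_PARAMS, local_align
from .seqio import AlignmentBlock, ProteinRecord

log = logging.getLogger(__name__)

_NEG = -1e30


@njit(cache=True)
def _global_profile_dp(S, open_first, extend):  # pragma: no cover - compiled
    """Global Gotoh on a precomputed column-pair score matrix.

    Returns ops (0 diag, 1 column from A only, 2 column from B only) in
    reverse order.
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in B: consumes A column
    Iy = np.full((m + 1, n + 1), _NEG)  # gap in A: consumes B column
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = -open_first - (i - 1) * extend
        ptrX[i, 0] = 1
    for j in range(1, n + 1):
        Iy[0, j] = -open_first - (j - 1) * extend
        ptrY[0, j] = 2
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # match state
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            ptrM[i, j] = p
            # gap in B (A column against gaps)
            bx = M[i - 1, j] - open_first
            px = 0
            if Ix[i - 1, j] - extend > bx:
                bx = Ix[i - 1, j] - extend
                px = 1
            if Iy[i - 1, j] - open_first > bx:
                bx = Iy[i - 1, j] - open_first
                px = 2
            Ix[i, j] = bx
            ptrX[i, j] = px
            # gap in A
            by = M[i, j - 1] - open_first
            py = 0
            if Iy[i, j - 1] - extend > by:
                by = Iy[i, j - 1] - extend
                py = 2
            if Ix[i, j - 1] - open_first > by:
                by = Ix[i, j - 1] - open_first
                py = 1
            Iy[i, j] = by
            ptrY[i, j] = py
    # traceback
    state = 0
    best = M[m, n]
    if Ix[m, n] > best:
        best = Ix[m, n]
        state = 1
    if Iy[m, n] > best:
        best = Iy[m, n]
        state = 2
    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            p = ptrM[i, j]
            i -= 1
            j -= 1
            state = p
        elif state == 1:
            ops[k] = 1
            p = ptrX[i, j]
            i -= 1
            state = 0 if p == 0 else (1 if p == 1 else 2)
        else:
            ops[k] = 2
            p = ptrY[i, j]
            j -= 1
            state = 0 if p == 0 else (1 if p == 1 else 2)
        k += 1
    return ops[:k], best


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(ncols, 21) occupancy-weighted residue frequencies of a sub-alignment."""
    ncols = len(rows[0])
    out = np.zeros((ncols, len(ALPHABET)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                out[c, AA_INDEX[ch]] += 1.0
    return out / len(rows)


def _merge(blockA: list[tuple[str, str]], blockB: list[tuple[str, str]],
           params: AlignParams) -> list[tuple[str, str]]:
    fa = _profile_freqs([s for _, s in blockA])
    fb = _profile_freqs([s for _, s in blockB])
    S = fa @ BLOSUM62.astype(np.float64) @ fb.T
    ops, _ = _global_profile_dp(S, float(params.open_first), float(params.gap_extend))
    ops = ops[::-1]
    outA = [[] for _ in blockA]
    outB = [[] for _ in blockB]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for r, (_, s) in zip(outA, blockA):
                r.append(s[ia])
            for r, (_, s) in zip(outB, blockB):
                r.append(s[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for r, (_, s) in zip(outA, blockA):
                r.append(s[ia])
            for r in outB:
                r.append("-")
            ia += 1
        else:
            for r in outA:
                r.append("-")
            for r, (_, s) in zip(outB, blockB):
                r.append(s[ib])
            ib += 1
    rows = [(rid, "".join(r)) for (rid, _), r in zip(blockA, outA)]
    rows += [(rid, "".join(r)) for (rid, _), r in zip(blockB, outB)]
    return rows


def global_align_pair(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> tuple[str, str]:
    """Global pairwise alignment of two plain sequences (the degenerate
    two-leaf case of the progressive aligner)."""
    rows = _merge([("a", a)], [("b", b)], params)
    return rows[0][1], rows[1][1]


def progressive_align(
    family: OrthologFamily | list[ProteinRecord],
    params: AlignParams = DEFAULT_PARAMS,
) -> AlignmentBlock:
    """Align all family members; rows come back in family order.

    Guide tree: UPGMA (average linkage) on d = 1 − %identity/100 from the
    exact local aligner.  Single-member families yield a trivial one-row
    block with a warning.
    """
    members = family.members() if isinstance(family, OrthologFamily) else list(family)
    if not members:
        raise ValueError("empty family")
    if len(members) == 1:
        log.warning("single-sequence family %s: trivial alignment", members[0].id)
        return AlignmentBlock(rows=[(members[0].id, members[0].seq)])
    if len(members) == 2:
        ra, rb = global_align_pair(members[0].seq, members[1].seq, params)
        return AlignmentBlock(rows=[(members[0].id, ra), (members[1].id, rb)])

    n = len(members)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        hit = local_align(members[i], members[j], params)
        dist[i, j] = dist[j, i] = 1.0 - hit.pct_identity / 100.0
    Z = linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, list[tuple[str, str]]] = {
        i: [(m.id, m.seq)] for i, m in enumerate(members)
    }
    for k, (a, b, _, _) in enumerate(Z):
        clusters[n + k] = _merge(clusters.pop(int(a)), clusters.pop(int(b)), params)
    rows = clusters[2 * n - 2]
    by_id = dict(rows)
    return AlignmentBlock(rows=[(m.id, by_id[m.id]) for m in members])


def map_domain_to_columns(block: AlignmentBlock, ref_id: str,
                          domain_interval: tuple[int, int]) -> np.ndarray:
    """1-based alignment columns carrying reference residues start..end.

    The result is strictly increasing with exactly domain-length entries.
    """
    start, end = domain_interval
    row = block.row(ref_id)
    unglen = len(row) - row.count("-")
    if not (1 <= start <= end <= unglen):
        raise ValueError(
            f"domain {start}..{end} outside reference length {unglen}"
        )
    cols = []
    pos = 0
    for c, ch in enumerate(row, start=1):
        if ch != "-":
            pos += 1
            if start <= pos <= end:
                cols.append(c)
            if pos > end:
                break
    return np.array(cols, dtype=int)
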