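"""Amino-acid alphabet and integer-encoded BLOSUM62 for the fast aligners."""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

# 20 canonical residues plus X (unknown).  Order is fixed: encodings, frequency
# tables and the substitution matrix all index into this string.
ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# residues folded to X on input (per config; see seqio.sanitize_seq)
AMBIGUOUS = set("BZUOJ")

_ENC = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENC[ord(_aa)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an upper-case amino-acid string as int8 indices into ALPHABET."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(arr < 0)[0]})
        raise ValueError(f"non-canonical residues {bad}; sanitize input first")
    return arr


def blosum62() -> np.ndarray:
    """BLOSUM62 as an int32 matrix over ALPHABET (incl. X column/row)."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(mat[a][b])
    return out


BLOSUM62 = blosum62()
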