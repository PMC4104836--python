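"""Shared Smith-Waterman dynamic-programming kernels.

Both the pairwise aligner and the profile search reduce to a local
alignment over a query whose positions carry a 21-vector of per-residue
scores (``qrows``): for pairwise alignment qrows is the substitution
matrix indexed by the query's residue codes, for a profile it is the
position-specific log-odds table. Column 20 is the ``X`` wildcard and
scores 0 by convention.

Gap model: a gap of length L costs ``gap_open + L * gap_extend`` (the
NCBI BLAST convention, under which the published Karlin-Altschul
constants for BLOSUM62 with 11/1 gaps apply).

Traceback ties are broken diagonal > up (gap in target) > left (gap in
query); the maximal cell is the first maximum in row-major order. Both
choices make the reported alignment deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .io import AMINO_ACIDS

NEG = -1.0e30

#: residue letter -> code 0..20 (X = 20)
RESIDUE_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
RESIDUE_CODE["X"] = 20
N_CODES = 21


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as uint8 codes."""
    return np.fromiter((RESIDUE_CODE[ch] for ch in residues), dtype=np.uint8,
                       count=len(residues))


@njit(cache=True, fastmath=True)
def sw_score(qrows, cb, gap_open, gap_extend):
    """Score-only affine local alignment.

    Parameters: qrows (m, 21) per-query-position scores; cb target codes;
    positive gap penalties. Returns the optimal score (>= 0).
    """
    m = qrows.shape[0]
    n = cb.shape[0]
    H = np.zeros(n + 1)
    F = np.full(n + 1, NEG)
    go = gap_open + gap_extend
    best = 0.0
    for i in range(m):
        row = qrows[i]
        e = NEG
        diag = 0.0  # H[i-1, j-1]
        h_left = 0.0  # H[i, j-1]
        for j in range(1, n + 1):
            a = h_left - go
            b = e - gap_extend
            e = a if a > b else b
            up = H[j]  # H[i-1, j]
            a = up - go
            b = F[j] - gap_extend
            f = a if a > b else b
            F[j] = f
            v = diag + row[cb[j - 1]]
            if f > v:
                v = f
            if e > v:
                v = e
            if v < 0.0:
                v = 0.0
            H[j] = v
            h_left = v
            diag = up
            if v > best:
                best = v
    return best


@njit(cache=True, fastmath=False)
def sw_align(qrows, ca, cb, gap_open, gap_extend):
    """Full affine local alignment with deterministic traceback.

    ``ca`` are the query residue codes used only to count identities
    (pass an all-255 array for profile queries, where identity is
    meaningless). Returns
    ``(score, q_start, q_end, t_start, t_end, matches, columns)`` with
    1-based inclusive coordinates; all-zero coordinates denote an empty
    (score 0) alignment.
    """
    m = qrows.shape[0]
    n = cb.shape[0]
    H = np.zeros(n + 1)
    F = np.full(n + 1, NEG)
    # packed pointers per cell: bits 0-1 H source (0 stop, 1 diag, 2 up/F,
    # 3 left/E), bit 2 F opened from H, bit 3 E opened from H
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    go = gap_open + gap_extend
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        row = qrows[i - 1]
        e_cur = NEG
        diag = 0.0   # H[i-1, j-1]
        h_left = 0.0  # H[i, j-1]
        for j in range(1, n + 1):
            bits = 0
            a = h_left - go
            b = e_cur - gap_extend
            if a >= b:
                e_cur = a
                bits |= 8
            else:
                e_cur = b
            up = H[j]  # H[i-1, j]
            a = up - go
            b = F[j] - gap_extend
            if a >= b:
                F[j] = a
                bits |= 4
            else:
                F[j] = b
            d = diag + row[cb[j - 1]]
            # tie-break: diagonal > up > left, stop at 0
            v = d
            p = 1
            if F[j] > v:
                v = F[j]
                p = 2
            if e_cur > v:
                v = e_cur
                p = 3
            if v <= 0.0:
                v = 0.0
                p = 0
            H[j] = v
            h_left = v
            diag = up
            ptr[i, j] = bits | p
            if v > best:
                best = v
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    cols = 0
    matches = 0
    state = 0  # 0 = H, 2 = F chain (up), 3 = E chain (left)
    while True:
        if state == 0:
            p = ptr[i, j] & 3
            if p == 0:
                break
            if p == 1:
                cols += 1
                if ca[i - 1] == cb[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            cols += 1
            opened = ptr[i, j] & 4
            i -= 1
            if opened:
                state = 0
        else:
            cols += 1
            opened = ptr[i, j] & 8
            j -= 1
            if opened:
                state = 0
    return best, i + 1, bi, j + 1, bj, matches, cols
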