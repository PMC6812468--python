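"""Numba kernel for k-banded local alignment with affine gaps.

The dynamic program fills only a band of cells around a center diagonal
(diagonal of cell (i, j) = i - j, query index minus subject index), so the
cost is O(band_width * min(n, m)) instead of O(n * m).  Storage is
band-compressed: along a diagonal the band coordinate b = j - i + center + w
is constant, which keeps the arrays at (n + 1) x (band_width + 2).

Gap model: a gap of length L costs gap_open + gap_extend * L.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(10 ** 9)

# traceback codes for the H (match) layer
_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3


@njit(cache=True)
def banded_sw(q, s, matrix, gap_open, gap_extend, center_diag, half_width):
    """Banded Smith-Waterman over encoded sequences.

    Parameters are integer-encoded residue arrays, an integer substitution
    matrix, positive gap penalties, the band's center diagonal (q_pos - s_pos)
    and half-width.  Returns
    ``(raw_score, q_start, q_end, s_start, s_end, aln_length, identities,
    mismatches, gap_opens)`` with 1-based inclusive coordinates, or zeros when
    no cell scores above 0.
    """
    n = q.shape[0]
    m = s.shape[0]
    w = half_width
    width = 2 * w + 1

    # layers: H best-ending-here, E gap in query (j moves), F gap in subject
    H = np.full((n + 1, width), 0, dtype=np.int64)
    E = np.full((n + 1, width), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, width), NEG_INF, dtype=np.int64)
    ptrH = np.zeros((n + 1, width), dtype=np.int8)
    ptrE = np.zeros((n + 1, width), dtype=np.int8)  # 1 = extend existing gap
    ptrF = np.zeros((n + 1, width), dtype=np.int8)

    open_cost = gap_open + gap_extend

    best = 0
    best_i = 0
    best_b = 0

    for i in range(1, n + 1):
        # subject columns j (1-based) within the band for this row
        j_lo = i - center_diag - w
        j_hi = i - center_diag + w
        if j_lo < 1:
            j_lo = 1
        if j_hi > m:
            j_hi = m
        for j in range(j_lo, j_hi + 1):
            b = j - i + center_diag + w  # 0..2w by construction

            # E: gap in the query (come from (i, j-1) => band b-1)
            e_val = NEG_INF
            e_ptr = 0
            if b - 1 >= 0:
                from_open = H[i, b - 1] - open_cost
                from_ext = E[i, b - 1] - gap_extend
                if from_ext > from_open:
                    e_val = from_ext
                    e_ptr = 1
                else:
                    e_val = from_open
            E[i, b] = e_val
            ptrE[i, b] = e_ptr

            # F: gap in the subject (come from (i-1, j) => band b+1)
            f_val = NEG_INF
            f_ptr = 0
            if b + 1 < width:
                from_open = H[i - 1, b + 1] - open_cost
                from_ext = F[i - 1, b + 1] - gap_extend
                if from_ext > from_open:
                    f_val = from_ext
                    f_ptr = 1
                else:
                    f_val = from_open
            F[i, b] = f_val
            ptrF[i, b] = f_ptr

            diag = H[i - 1, b] + matrix[q[i - 1], s[j - 1]]

            h = 0
            p = _STOP
            if diag > h:
                h = diag
                p = _DIAG
            if e_val > h:
                h = e_val
                p = _FROM_E
            if f_val > h:
                h = f_val
                p = _FROM_F
            H[i, b] = h
            ptrH[i, b] = p

            if h > best:
                best = h
                best_i = i
                best_b = b

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0

    # traceback
    i = best_i
    b = best_b
    layer = 0  # 0 = H, 1 = E, 2 = F
    aln_len = 0
    identities = 0
    mismatches = 0
    gap_opens = 0
    q_end = best_i
    s_end = best_b + best_i - center_diag - w
    while True:
        j = b + i - center_diag - w
        if layer == 0:
            p = ptrH[i, b]
            if p == _STOP:
                break
            if p == _DIAG:
                aln_len += 1
                if q[i - 1] == s[j - 1]:
                    identities += 1
                else:
                    mismatches += 1
                i -= 1
                # b unchanged along the diagonal
            elif p == _FROM_E:
                layer = 1
            else:
                layer = 2
        elif layer == 1:
            aln_len += 1  # gap column: subject residue against a query gap
            if ptrE[i, b] == 0:
                layer = 0
                gap_opens += 1
            b -= 1
        else:
            aln_len += 1  # gap column: query residue against a subject gap
            if ptrF[i, b] == 0:
                layer = 0
                gap_opens += 1
            i -= 1
            b += 1

    q_start = i + 1
    s_start = (b + i - center_diag - w) + 1
    return (
        best,
        q_start,
        q_end,
        s_start,
        s_end,
        aln_len,
        identities,
        mismatches,
        gap_opens,
    )
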