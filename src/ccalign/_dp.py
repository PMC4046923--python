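"""Numba kernels for the modified Smith-Waterman-Gotoh local aligner.

The aligner differs from the textbook algorithm only in how the
substitution score of a residue pair is looked up: the matrix is chosen
per pair according to the coiled-coil state of the two residues (and,
in register-aware mode, the heptad register of the more confidently
predicted residue), and a bonus is added when the predicted registers
of the two residues agree.

Gap costs follow the BLAST convention: a gap of length g costs
open + g * extend, i.e. the first gapped position costs open + extend.

Tie-breaks are fixed for determinism: diagonal > up (gap in subject) >
left (gap in query) when traceback pointers are assigned, and the best
cell is the first maximum in row-major order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2 ** 30))

# score-grid tags (indices into the MatrixSet score stack)
TAG_NONCC, TAG_FULL, TAG_CC, TAG_AD, TAG_EG, TAG_BCF = 0, 1, 2, 3, 4, 5


@njit(cache=True)
def build_score_grid(ca, cb, cca, ccb, ga, gb, ra, rb, pa, pb,
                     stack, bonus, use_cc):
    """Per-pair substitution scores S[i, j] for all residue pairs.

    ``ca/cb``: residue codes (0..19, 20 = X); ``cca/ccb``: coiled-coil
    state; ``ga/gb``: register-group index (0 AD, 1 EG, 2 BCF, -1 none);
    ``ra/rb``: register index (0..6, -1 none); ``pa/pb``: coiled-coil
    probabilities.  With ``use_cc`` false only ``stack[0]`` is used
    (plain mode).
    """
    na = ca.shape[0]
    nb = cb.shape[0]
    S = np.empty((na, nb), dtype=np.int32)
    for i in range(na):
        ai = ca[i]
        for j in range(nb):
            bj = cb[j]
            if not use_cc:
                S[i, j] = stack[0, ai, bj]
                continue
            if cca[i] and ccb[j]:
                g = ga[i] if pa[i] >= pb[j] else gb[j]
                t = TAG_CC if g < 0 else TAG_AD + g
                s = stack[t, ai, bj]
                if bonus > 0 and ra[i] >= 0 and ra[i] == rb[j]:
                    s += bonus
                S[i, j] = s
            elif (not cca[i]) and (not ccb[j]):
                S[i, j] = stack[TAG_NONCC, ai, bj]
            else:
                S[i, j] = stack[TAG_FULL, ai, bj]
    return S


@njit(cache=True)
def gotoh_best(S, gap_open, gap_extend):
    """Best local alignment score (and end cell) under affine gaps."""
    na, nb = S.shape
    go = gap_open + gap_extend  # opening a gap costs open + extend
    ge = gap_extend
    H = np.zeros(nb + 1, dtype=np.int32)
    F = np.full(nb + 1, NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, na + 1):
        prev_diag = np.int32(0)
        hleft = np.int32(0)
        E = NEG
        for j in range(1, nb + 1):
            f = H[j] - go
            fe = F[j] - ge
            if fe > f:
                f = fe
            F[j] = f
            e = hleft - go
            ee = E - ge
            if ee > e:
                e = ee
            E = e
            h = prev_diag + S[i - 1, j - 1]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = np.int32(0)
            prev_diag = H[j]
            H[j] = h
            hleft = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def gotoh_pointers(S, gap_open, gap_extend):
    """Full DP with traceback pointers.

    ptr_h: 0 start-of-alignment, 1 diagonal, 2 up (from F), 3 left (from E).
    ptr_f / ptr_e: 1 gap opened from H, 0 gap extended.
    """
    na, nb = S.shape
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.zeros((na + 1, nb + 1), dtype=np.int32)
    E = np.full((na + 1, nb + 1), NEG, dtype=np.int32)
    F = np.full((na + 1, nb + 1), NEG, dtype=np.int32)
    ptr_h = np.zeros((na + 1, nb + 1), dtype=np.uint8)
    ptr_e = np.zeros((na + 1, nb + 1), dtype=np.uint8)
    ptr_f = np.zeros((na + 1, nb + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            fo = H[i - 1, j] - go
            fx = F[i - 1, j] - ge
            if fo >= fx:
                F[i, j] = fo
                ptr_f[i, j] = 1
            else:
                F[i, j] = fx
                ptr_f[i, j] = 0
            eo = H[i, j - 1] - go
            ex = E[i, j - 1] - ge
            if eo >= ex:
                E[i, j] = eo
                ptr_e[i, j] = 1
            else:
                E[i, j] = ex
                ptr_e[i, j] = 0
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            # preference: diagonal > up > left > stop
            h = np.int32(0)
            p = np.uint8(0)
            if d >= h and d >= F[i, j] and d >= E[i, j]:
                h = d
                p = np.uint8(1)
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h = F[i, j]
                p = np.uint8(2)
            elif E[i, j] >= h:
                h = E[i, j]
                p = np.uint8(3)
            if h <= 0:
                h = np.int32(0)
                p = np.uint8(0)
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr_h, ptr_e, ptr_f
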