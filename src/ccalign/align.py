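"""Coiled-coil-aware local alignment of a protein pair.

Three modes:

``plain``
    Textbook Smith-Waterman-Gotoh with one fixed matrix (no
    compositional adjustment, no coiled-coil awareness).
``ccalign``
    The pair is partitioned into coiled-coil and non-coiled-coil
    sections; compositionally adjusted matrices are computed for the
    coiled-coil pair, the non-coiled-coil pair and the full-length pair,
    and the matrix for each residue pair is selected by the coiled-coil
    state of the two residues (both coiled-coil -> coiled-coil matrix;
    neither -> non-coiled-coil matrix; mixed -> full-length matrix).
``ccalignx``
    As ``ccalign``, but coiled-coil residues are further split by heptad
    register group (a/d, e/g, b/c/f).  For a coiled-coil residue pair the
    matrix of the register group of the more confidently predicted
    residue is used, and a bonus score is awarded when the two predicted
    registers agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .matrices import (
    DEFAULT_GROUP_ENTROPIES,
    MIN_REGION_LENGTH,
    MatrixSet,
    ScoreMatrix,
    adjust_matrix,
    blosum62,
    compute_composition,
    compute_register_weights,
)
from .seq import (
    GROUPS,
    NO_REGISTER,
    REGISTERS,
    AnnotatedProtein,
    encode_sequence,
    extract_subsequences,
    partition_protein,
)

#: Karlin-Altschul parameters for gapped BLOSUM62 with gap costs 11/1
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

MODES = ("plain", "ccalign", "ccalignx")

_GROUP_INDEX = {"AD": 0, "EG": 1, "BCF": 2}
_REG_INDEX = {r: i for i, r in enumerate(REGISTERS)}


@dataclass
class AlignParams:
    """Alignment parameters (defaults follow the published settings where
    stated: coiled-coil probability cutoff 0.8; BLAST protein gap costs
    11/1; median-normalized register weights; one half-bit register
    bonus)."""

    mode: str = "ccalign"
    cc_cutoff: float = 0.8
    gap_open: int = 11
    gap_extend: int = 1
    weights_scheme: str = "median"
    bonus: int = 1
    lambda_k: tuple[float, float] = (DEFAULT_LAMBDA, DEFAULT_K)
    adjust: bool = True
    min_region_length: int = MIN_REGION_LENGTH

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.bonus < 0:
            raise ValueError("bonus must be >= 0")


@dataclass
class AlignedPair:
    """One aligned residue pair with its matrix tag."""

    q_pos: int  # 1-based
    s_pos: int
    tag: str  # CC, NONCC, MIXED, AD, EG, BCF
    weight_group: str | None  # group whose weighted matrix scored the pair
    bonus: bool


@dataclass
class Alignment:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    pairs: list[AlignedPair] = field(default_factory=list)
    n_bonus: int = 0
    n_identical: int = 0
    length: int = 0  # alignment columns incl. gaps

    @property
    def pident(self) -> float:
        return 100.0 * self.n_identical / self.length if self.length else 0.0

    @property
    def is_empty(self) -> bool:
        return self.raw_score == 0 and not self.pairs


def bit_score(raw: float, lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """Normalized (bit) score: (lambda * raw - ln K) / ln 2."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be > 0")
    return (lam * raw - math.log(K)) / math.log(2.0)


def select_matrix(state_i: bool, state_j: bool, reg_i: str, reg_j: str,
                  prob_i: float, prob_j: float, mset: MatrixSet,
                  mode: str) -> tuple[str, bool]:
    """Matrix tag and bonus flag for one residue pair.

    Both coiled-coil: ``ccalign`` uses the coiled-coil matrix; ``ccalignx``
    uses the register-group matrix of the more confident prediction
    (query wins ties).  Neither: non-coiled-coil matrix.  Mixed: the
    full-length matrix.  The bonus applies only in ``ccalignx`` mode when
    both registers are annotated and equal.
    """
    from .seq import GROUP_OF_REGISTER

    if state_i and state_j:
        reg = reg_i if prob_i >= prob_j else reg_j
        group = GROUP_OF_REGISTER.get(reg)
        bonus = mode == "ccalignx" and reg_i == reg_j and reg_i != NO_REGISTER
        if mode == "ccalignx":
            return (group if group is not None else "CC"), bonus
        return "CC", False
    if not state_i and not state_j:
        return "NONCC", False
    return "MIXED", False


def _region_composition(sub: dict[str, str], key: str, full_key: str,
                        min_len: int):
    """Composition of a region, falling back to a longer region when the
    subsequence is too short for stable adjustment."""
    seq = sub[key]
    if len(seq) >= min_len:
        return compute_composition(seq), key
    return compute_composition(sub[full_key]), full_key


def build_matrix_set(A: AnnotatedProtein, B: AnnotatedProtein,
                     params: AlignParams,
                     base: ScoreMatrix | None = None) -> MatrixSet:
    """Adjusted matrices for the ordered pair (A, B).

    Regions shorter than ``params.min_region_length`` re-use the
    full-length compositions; register groups additionally fall back to
    the generic coiled-coil matrix.  With ``params.adjust`` false the
    base matrix is used everywhere (plain mode always scores with the
    unadjusted base).
    """
    if base is None:
        base = blosum62()
    if params.mode == "plain" or not params.adjust:
        weights = None
        if params.mode != "plain" and params.weights_scheme != "off":
            weights = compute_register_weights(DEFAULT_GROUP_ENTROPIES,
                                               params.weights_scheme)
        return MatrixSet(m_cc=base, m_noncc=base, m_full=base,
                         m_group={g: base for g in GROUPS},
                         weights=weights,
                         bonus=params.bonus if params.mode == "ccalignx" else 0)

    part_a = partition_protein(A, params.cc_cutoff)
    part_b = partition_protein(B, params.cc_cutoff)
    sub_a = extract_subsequences(A, part_a, params.cc_cutoff)
    sub_b = extract_subsequences(B, part_b, params.cc_cutoff)
    sub_a["full"] = A.residues
    sub_b["full"] = B.residues
    min_len = params.min_region_length

    c_full_a = compute_composition(sub_a["full"])
    c_full_b = compute_composition(sub_b["full"])
    m_full = adjust_matrix(base, c_full_a, c_full_b)

    def region_matrix(key: str) -> ScoreMatrix:
        ca, ka = _region_composition(sub_a, key, "full", min_len)
        cb, kb = _region_composition(sub_b, key, "full", min_len)
        if ka == "full" and kb == "full":
            return m_full
        return adjust_matrix(base, ca, cb)

    m_cc = region_matrix("cc")
    m_noncc = region_matrix("noncc")

    m_group = None
    if params.mode == "ccalignx":
        m_group = {}
        for g in GROUPS:
            # short group subsequences fall back to the generic
            # coiled-coil matrix rather than the full-length one
            if len(sub_a[g]) >= min_len and len(sub_b[g]) >= min_len:
                m_group[g] = adjust_matrix(base, compute_composition(sub_a[g]),
                                           compute_composition(sub_b[g]))
            else:
                m_group[g] = m_cc

    weights = None
    if params.weights_scheme != "off":
        weights = compute_register_weights(DEFAULT_GROUP_ENTROPIES,
                                           params.weights_scheme)
    return MatrixSet(m_cc=m_cc, m_noncc=m_noncc, m_full=m_full,
                     m_group=m_group, weights=weights,
                     bonus=params.bonus if params.mode == "ccalignx" else 0)


def _dp_arrays(p: AnnotatedProtein, cutoff: float):
    codes = encode_sequence(p.residues)
    cc = p.cc_mask(cutoff).astype(np.uint8)
    reg_eff = p.effective_register(cutoff)
    grp = np.full(len(p), -1, dtype=np.int8)
    reg = np.full(len(p), -1, dtype=np.int8)
    from .seq import GROUP_OF_REGISTER

    for i, r in enumerate(reg_eff):
        if r != NO_REGISTER:
            reg[i] = _REG_INDEX[r]
            g = GROUP_OF_REGISTER.get(r)
            if g is not None:
                grp[i] = _GROUP_INDEX[g]
    prob = p.cc_prob.astype(np.float64)
    return codes, cc, grp, reg, prob


def score_grid(A: AnnotatedProtein, B: AnnotatedProtein, mset: MatrixSet,
               params: AlignParams) -> np.ndarray:
    """The per-pair substitution score grid the DP runs on."""
    ca, cca, ga, ra, pa = _dp_arrays(A, params.cc_cutoff)
    cb, ccb, gb, rb, pb = _dp_arrays(B, params.cc_cutoff)
    use_cc = params.mode != "plain"
    stack = mset.score_stack(params.mode)
    bonus = mset.bonus if params.mode == "ccalignx" else 0
    return _dp.build_score_grid(ca, cb, cca, ccb, ga, gb, ra, rb, pa, pb,
                                stack, np.int32(bonus), use_cc)


def align_score(A: AnnotatedProtein, B: AnnotatedProtein, mset: MatrixSet,
                params: AlignParams) -> int:
    """Raw local alignment score only (fast path for searches)."""
    if len(A) == 0 or len(B) == 0:
        return 0
    S = score_grid(A, B, mset, params)
    best, _, _ = _dp.gotoh_best(S, np.int32(params.gap_open),
                                np.int32(params.gap_extend))
    return int(best)


def align(A: AnnotatedProtein, B: AnnotatedProtein, mset: MatrixSet,
          params: AlignParams) -> Alignment:
    """Optimal local alignment of A (query) and B (subject)."""
    lam, K = params.lambda_k
    if len(A) == 0 or len(B) == 0:
        return Alignment(A.id, B.id, 0, bit_score(0, lam, K), 0, 0, 0, 0)
    S = score_grid(A, B, mset, params)
    best, bi, bj, ptr_h, ptr_e, ptr_f = _dp.gotoh_pointers(
        S, np.int32(params.gap_open), np.int32(params.gap_extend))
    if best <= 0:
        return Alignment(A.id, B.id, 0, bit_score(0, lam, K), 0, 0, 0, 0)

    cc_a = A.cc_mask(params.cc_cutoff)
    cc_b = B.cc_mask(params.cc_cutoff)
    reg_a = A.effective_register(params.cc_cutoff)
    reg_b = B.effective_register(params.cc_cutoff)

    pairs: list[AlignedPair] = []
    n_ident = 0
    n_cols = 0
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                tag, bonus = select_matrix(
                    bool(cc_a[i - 1]), bool(cc_b[j - 1]),
                    reg_a[i - 1], reg_b[j - 1],
                    A.cc_prob[i - 1], B.cc_prob[j - 1], mset, params.mode)
                wg = None
                if bool(cc_a[i - 1]) and bool(cc_b[j - 1]):
                    r = reg_a[i - 1] if A.cc_prob[i - 1] >= B.cc_prob[j - 1] \
                        else reg_b[j - 1]
                    from .seq import GROUP_OF_REGISTER
                    wg = GROUP_OF_REGISTER.get(r)
                pairs.append(AlignedPair(i, j, tag, wg,
                                         bonus and mset.bonus > 0))
                if A.residues[i - 1] == B.residues[j - 1]:
                    n_ident += 1
                n_cols += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject, consume query
            opened = ptr_f[i, j]
            i -= 1
            n_cols += 1
            if opened:
                state = "H"
        else:  # gap in query, consume subject
            opened = ptr_e[i, j]
            j -= 1
            n_cols += 1
            if opened:
                state = "H"
    pairs.reverse()
    q_start = pairs[0].q_pos if pairs else 0
    s_start = pairs[0].s_pos if pairs else 0
    return Alignment(A.id, B.id, int(best), bit_score(int(best), lam, K),
                     q_start, bi, s_start, bj, pairs=pairs,
                     n_bonus=sum(1 for p in pairs if p.bonus),
                     n_identical=n_ident, length=n_cols)


def align_pair(A: AnnotatedProtein, B: AnnotatedProtein,
               params: AlignParams | None = None,
               base: ScoreMatrix | None = None) -> Alignment:
    """Convenience wrapper: build the matrix set for (A, B) and align."""
    params = params or AlignParams()
    mset = build_matrix_set(A, B, params, base)
    return align(A, B, mset, params)
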