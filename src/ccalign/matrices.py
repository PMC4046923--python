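"""Substitution-matrix machinery.

The central operation is compositional adjustment: re-deriving the
substitution scores so that the implied joint residue-pair distribution
has the amino-acid compositions of the two sequences being aligned as
its marginals, while the matrix's relative entropy (the expected
log-odds score in bits, a proxy for the phylogenetic signal carried per
aligned pair) is held at the value of the base matrix.  Separate
adjusted matrices are computed for the coiled-coil sections, the
non-coiled-coil sections and the full-length proteins of a pair — and,
for register-aware alignment, for the three register groups of the
heptad repeat (a/d interface, e/g intermediate, b/c/f outside).

All scores use the BLOSUM62 half-bit convention so that base and
adjusted matrices are interchangeable within one alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from ._adjust import adjust_joint
from .seq import AA_ORDER, AA_INDEX, GROUPS


#: default pseudocount mass (one observation per amino acid) added to
#: observed compositions; prevents zero frequencies, which break the
#: log-odds machinery and the adjustment solver.
DEFAULT_PSEUDO_MASS = 20.0

#: regions shorter than this re-use the full-length adjusted matrix:
#: compositions estimated from fewer residues make the adjustment
#: unstable without adding usable signal.
MIN_REGION_LENGTH = 20


@dataclass
class CompositionVector:
    """Amino-acid composition (20 frequencies summing to one)."""

    freq: np.ndarray
    n_obs: float = 0.0

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (20,):
            raise ValueError("composition must have 20 entries")
        if self.freq.min() < 0 or abs(self.freq.sum() - 1.0) > 1e-8:
            raise ValueError("composition must be a probability vector")


@dataclass
class ScoreMatrix:
    """An integer substitution matrix with its underlying probabilities.

    ``scores[a][b] = round(log2(q_ab / (c1_a * c2_b)) / scale)`` for
    matrices constructed here; the shipped BLOSUM62 keeps the canonical
    published integers (the shipped frequency table is refined so that
    the identity holds for it as well).
    """

    name: str
    scores: np.ndarray
    joint_q: np.ndarray
    bg_row: np.ndarray
    bg_col: np.ndarray
    scale: float = 0.5
    converged: bool = True
    x_scores: np.ndarray | None = None  # length-21 vector: scores vs X, last = X/X

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int32)
        self.joint_q = np.asarray(self.joint_q, dtype=float)
        self.bg_row = np.asarray(self.bg_row, dtype=float)
        self.bg_col = np.asarray(self.bg_col, dtype=float)

    @property
    def rel_entropy_bits(self) -> float:
        return matrix_relative_entropy(self.joint_q, self.bg_row, self.bg_col)

    @property
    def log_odds(self) -> np.ndarray:
        """Unrounded log-odds in bits (zero joint entries floored)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = np.log2(self.joint_q / np.outer(self.bg_row, self.bg_col))
        lod[~np.isfinite(lod)] = -8.0
        return lod

    @classmethod
    def from_joint(cls, joint_q: np.ndarray, *, name: str = "",
                   scale: float = 0.5, converged: bool = True,
                   x_scores: np.ndarray | None = None) -> "ScoreMatrix":
        joint_q = np.asarray(joint_q, dtype=float)
        bg_row = joint_q.sum(axis=1)
        bg_col = joint_q.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = np.log2(joint_q / np.outer(bg_row, bg_col))
        # unobserved pairs (q = 0) get a strongly negative floor score
        lod[~np.isfinite(lod)] = -8.0
        scores = np.round(lod / scale)
        return cls(name=name, scores=scores.astype(np.int32), joint_q=joint_q,
                   bg_row=bg_row, bg_col=bg_col, scale=scale,
                   converged=converged, x_scores=x_scores)

    def scaled_scores(self, weight: float) -> np.ndarray:
        """Integer scores with the log-odds scaled by ``weight`` before
        rounding (register weighting happens on the unrounded scale)."""
        if weight == 1.0:
            return self.scores.copy()
        return np.round(weight * self.log_odds / self.scale).astype(np.int32)

    def extended_scores(self, weight: float = 1.0) -> np.ndarray:
        """21x21 integer scores; index 20 is X, scored from the base
        matrix's X column (never adjusted or weighted)."""
        out = np.empty((21, 21), dtype=np.int32)
        out[:20, :20] = self.scaled_scores(weight)
        x = self.x_scores if self.x_scores is not None else blosum62().x_scores
        out[:20, 20] = x[:20]
        out[20, :20] = x[:20]
        out[20, 20] = x[20]
        return out


def matrix_relative_entropy(joint_q: np.ndarray, c1: np.ndarray,
                            c2: np.ndarray) -> float:
    """Relative entropy H = sum_ab q_ab log2(q_ab / (c1_a c2_b)), in bits.

    Zero joint entries contribute zero (x log x -> 0 limit convention).
    """
    q = np.asarray(joint_q, dtype=float)
    pp = np.outer(np.asarray(c1, dtype=float), np.asarray(c2, dtype=float))
    mask = q > 0
    return float(np.sum(q[mask] * np.log2(q[mask] / pp[mask])))


def compute_composition(seq: str, pseudo_mass: float = DEFAULT_PSEUDO_MASS,
                        background: CompositionVector | None = None) -> CompositionVector:
    """Pseudocounted amino-acid composition of a sequence.

    ``freq_a = (count_a + pseudo_mass * bg_a) / (n + pseudo_mass)``;
    X and other non-standard letters are excluded from the counts.  An
    empty sequence returns the background unchanged.
    """
    if pseudo_mass < 0:
        raise ValueError("pseudo_mass must be >= 0")
    if background is None:
        bg = blosum62().bg_row
    else:
        bg = background.freq
    counts = np.zeros(20)
    for ch in seq:
        i = AA_INDEX.get(ch)
        if i is not None:
            counts[i] += 1
    n = counts.sum()
    if n == 0:
        return CompositionVector(freq=bg.copy(), n_obs=0.0)
    freq = (counts + pseudo_mass * bg) / (n + pseudo_mass)
    return CompositionVector(freq=freq, n_obs=float(n))


def adjust_matrix(base: ScoreMatrix, c1: CompositionVector, c2: CompositionVector,
                  *, max_iter: int = 100, tol: float = 1e-10) -> ScoreMatrix:
    """Compositionally adjust ``base`` to the compositions (c1, c2).

    The adjusted joint distribution minimizes KL divergence from the
    base joint distribution subject to the marginal constraints and to
    the base matrix's relative entropy.  If the solver fails (e.g. the
    entropy target is unreachable for extreme compositions) the base
    matrix is returned with ``converged = False``.
    """
    if c1.freq.min() <= 0 or c2.freq.min() <= 0:
        raise ValueError("compositions must be strictly positive (pseudocount them)")
    q, ok = adjust_joint(base.joint_q, c1.freq, c2.freq,
                         base.rel_entropy_bits, max_outer=max_iter, tol=tol)
    if not ok:
        out = ScoreMatrix(name=base.name + "|unadjusted", scores=base.scores.copy(),
                          joint_q=base.joint_q.copy(), bg_row=base.bg_row.copy(),
                          bg_col=base.bg_col.copy(), scale=base.scale,
                          converged=False, x_scores=base.x_scores)
        return out
    out = ScoreMatrix.from_joint(q, name=base.name + "|adjusted", scale=base.scale,
                                 x_scores=base.x_scores)
    return out


# ---------------------------------------------------------------------------
# shipped BLOSUM62 data
# ---------------------------------------------------------------------------

def _data_text(fname: str) -> str:
    return resources.files("ccalign.data").joinpath(fname).read_text()


@lru_cache(maxsize=1)
def blosum62() -> ScoreMatrix:
    """The standard BLOSUM62 matrix with joint/background frequencies.

    Scores are the canonical published integers; the joint target
    frequencies are shipped alongside (see the data file header) and are
    exactly consistent with the integers under half-bit rounding.  Its
    relative entropy is 0.70 bits (2 d.p.).
    """
    # scores (NCBI text format, incl. the X column)
    scores24, alpha = _parse_ncbi_matrix(_data_text("BLOSUM62.txt"))
    idx = [alpha.index(a) for a in AA_ORDER]
    xi = alpha.index("X")
    scores = scores24[np.ix_(idx, idx)]
    x_scores = np.empty(21, dtype=np.int32)
    x_scores[:20] = scores24[idx, xi]
    x_scores[20] = scores24[xi, xi]
    # joint frequencies
    q = np.zeros((20, 20))
    for line in _data_text("blosum62_freqs.tsv").splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        i = AA_INDEX[parts[0]]
        for j, v in enumerate(parts[1:]):
            q[i, j] = q[j, i] = float(v)
    return ScoreMatrix(name="BLOSUM62", scores=scores, joint_q=q,
                       bg_row=q.sum(axis=1), bg_col=q.sum(axis=0),
                       scale=0.5, x_scores=x_scores)


def _parse_ncbi_matrix(text: str) -> tuple[np.ndarray, list[str]]:
    alpha: list[str] = []
    rows: list[list[int]] = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        if not alpha:
            alpha = parts
            continue
        rows.append([int(x) for x in parts[1:]])
    return np.array(rows, dtype=np.int32), alpha


def write_ncbi_matrix(m: ScoreMatrix, path) -> None:
    """Write the 20x20 scores (plus X) in NCBI matrix text format."""
    letters = list(AA_ORDER) + ["X"]
    ext = m.extended_scores()
    with open(path, "w") as fh:
        fh.write(f"# {m.name} (half-bit scores)\n")
        fh.write("   " + "  ".join(letters) + "\n")
        for i, a in enumerate(letters):
            fh.write(a + " " + " ".join(f"{int(v):2d}" for v in ext[i]) + "\n")


def read_matrix(path) -> ScoreMatrix:
    """Read an NCBI-format score matrix; joint frequencies are
    reconstructed from the scores at the half-bit scale against the
    BLOSUM62 background (exact round-trip requires the sidecar TSV
    written by :func:`write_matrix_with_freqs`)."""
    with open(path) as fh:
        scores, alpha = _parse_ncbi_matrix(fh.read())
    idx = [alpha.index(a) for a in AA_ORDER]
    s = scores[np.ix_(idx, idx)]
    bg = blosum62().bg_row
    q = np.outer(bg, bg) * 2.0 ** (0.5 * s)
    q /= q.sum()
    return ScoreMatrix(name=str(path), scores=s, joint_q=q,
                       bg_row=q.sum(axis=1), bg_col=q.sum(axis=0))


def write_matrix_with_freqs(m: ScoreMatrix, matrix_path, freqs_path) -> None:
    """NCBI matrix file plus a sidecar TSV holding q_ab and both
    compositions, for lossless round-trips."""
    write_ncbi_matrix(m, matrix_path)
    with open(freqs_path, "w") as fh:
        fh.write("# sidecar frequencies for " + m.name + "\n")
        fh.write("# bg_row\t" + "\t".join(repr(float(x)) for x in m.bg_row) + "\n")
        fh.write("# bg_col\t" + "\t".join(repr(float(x)) for x in m.bg_col) + "\n")
        for i in range(20):
            fh.write(AA_ORDER[i] + "\t" +
                     "\t".join(repr(float(x)) for x in m.joint_q[i]) + "\n")


def read_matrix_with_freqs(matrix_path, freqs_path) -> ScoreMatrix:
    with open(matrix_path) as fh:
        scores, alpha = _parse_ncbi_matrix(fh.read())
    idx = [alpha.index(a) for a in AA_ORDER]
    s = scores[np.ix_(idx, idx)]
    q = np.zeros((20, 20))
    bg_row = bg_col = None
    with open(freqs_path) as fh:
        for line in fh:
            if line.startswith("# bg_row"):
                bg_row = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("# bg_col"):
                bg_col = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                parts = line.rstrip("\n").split("\t")
                q[AA_INDEX[parts[0]]] = [float(x) for x in parts[1:]]
    return ScoreMatrix(name=str(matrix_path), scores=s, joint_q=q,
                       bg_row=bg_row, bg_col=bg_col)


# ---------------------------------------------------------------------------
# register-group matrices from curated block alignments
# ---------------------------------------------------------------------------

@dataclass
class Block:
    """A gapless aligned block of coiled-coil sequences with per-column
    heptad register labels."""

    name: str
    sequences: list[str]
    registers: str

    def __post_init__(self) -> None:
        width = len(self.registers)
        for s in self.sequences:
            if len(s) != width:
                raise ValueError(f"block {self.name}: rows must be gapless and equal length")


def _cluster_sequences(seqs: list[str], identity: float) -> np.ndarray:
    """Single-linkage clustering at a fractional identity threshold;
    returns cluster labels (mirrors the clustering used to build the
    BLOSUM series)."""
    n = len(seqs)
    labels = np.arange(n)
    width = len(seqs[0])
    for i in range(n):
        for j in range(i + 1, n):
            ident = sum(a == b for a, b in zip(seqs[i], seqs[j])) / width
            if ident >= identity:
                li, lj = labels[i], labels[j]
                if li != lj:
                    labels[labels == lj] = li
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def build_register_matrices(blocks: list[Block], clustering_identity: float = 0.62,
                            *, min_pairs: float = 30.0,
                            pseudo_pairs: float = 40.0) -> dict[str, ScoreMatrix]:
    """BLOSUM-style matrices restricted to the columns of each register group.

    Sequences within each block are clustered at ``clustering_identity``
    (fractional); residue pairs are counted between sequences of
    different clusters, each sequence weighted by 1/cluster size.  The
    weighted pair counts of the columns belonging to each register group
    are normalized into a joint distribution (with a small pseudocount
    mass spread according to the observed marginals), from which half-bit
    scores and the group relative entropy follow.
    """
    from .seq import GROUP_OF_REGISTER

    counts = {g: np.zeros((20, 20)) for g in GROUPS}
    npairs = {g: 0.0 for g in GROUPS}
    for block in blocks:
        labels = _cluster_sequences(block.sequences, clustering_identity)
        sizes = np.bincount(labels)
        weights = 1.0 / sizes[labels]
        enc = [np.array([AA_INDEX.get(c, -1) for c in s]) for s in block.sequences]
        n = len(block.sequences)
        for col, reg in enumerate(block.registers):
            group = GROUP_OF_REGISTER.get(reg)
            if group is None:
                raise ValueError(f"block {block.name}: column {col + 1} register "
                                 f"{reg!r} is not a-g")
            for i in range(n):
                ai = enc[i][col]
                if ai < 0:
                    continue
                for j in range(i + 1, n):
                    if labels[i] == labels[j]:
                        continue
                    aj = enc[j][col]
                    if aj < 0:
                        continue
                    w = weights[i] * weights[j]
                    counts[group][ai, aj] += 0.5 * w
                    counts[group][aj, ai] += 0.5 * w
                    npairs[group] += w

    out: dict[str, ScoreMatrix] = {}
    for g in GROUPS:
        if npairs[g] < min_pairs:
            raise ValueError(f"insufficient counts for register group {g} "
                             f"({npairs[g]:.1f} weighted pairs < {min_pairs})")
        c = counts[g]
        marg = c.sum(axis=1) + c.sum(axis=0)
        marg = marg / marg.sum()
        # spread the pseudocount mass according to the observed marginals,
        # floored by a uniform share so every pair frequency stays positive
        marg = 0.99 * marg + 0.01 / 20.0
        pseudo = pseudo_pairs * np.outer(marg, marg)
        q = c + pseudo
        q = q / q.sum()
        out[g] = ScoreMatrix.from_joint(q, name=f"CC-{g}")
    return out


def compute_register_weights(entropies: dict[str, float], scheme: str = "median",
                             h_background: float | None = None) -> dict[str, float]:
    """Weights for the phylogenetic signal of heptad register groups.

    ``median``: w_G = H_G / median(H); ``blosum``: w_G = H_G / H(BLOSUM62);
    ``off``: all ones.  The per-register variants use the same formulas
    with per-register keys.
    """
    if not entropies:
        raise ValueError("no entropies supplied")
    for k, v in entropies.items():
        if v <= 0:
            raise ValueError(f"entropy for {k} must be > 0")
    if scheme == "off":
        return {k: 1.0 for k in entropies}
    if scheme in ("median", "per_register_median"):
        denom = float(np.median(list(entropies.values())))
    elif scheme in ("blosum", "per_register_blosum"):
        denom = h_background if h_background is not None else blosum62().rel_entropy_bits
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return {k: v / denom for k, v in entropies.items()}


#: group relative entropies estimated from register-labelled conserved
#: blocks: the hydrophobic interface carries the most signal, the
#: hydrophilic outside the least, and all groups carry less than the
#: whole-protein background.  Used for the default register weights.
DEFAULT_GROUP_ENTROPIES = {"AD": 0.45, "EG": 0.32, "BCF": 0.28}


# ---------------------------------------------------------------------------
# the per-pair matrix bundle
# ---------------------------------------------------------------------------

@dataclass
class MatrixSet:
    """The bundle of adjusted matrices for one ordered protein pair."""

    m_cc: ScoreMatrix
    m_noncc: ScoreMatrix
    m_full: ScoreMatrix
    m_group: dict[str, ScoreMatrix] | None = None
    weights: dict[str, float] | None = None
    bonus: int = 0

    def __post_init__(self) -> None:
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise ValueError("register weights must be positive")
        if self.bonus < 0:
            raise ValueError("bonus must be >= 0")

    def score_stack(self, mode: str) -> np.ndarray:
        """Integer score matrices indexed by the DP's per-pair tag:

        0 NONCC, 1 FULL, 2 CC (generic, unweighted), 3 AD, 4 EG, 5 BCF.

        In ``ccalign`` mode the group slots hold weighted copies of the
        coiled-coil matrix; in ``ccalignx`` mode they hold the weighted
        register-group matrices.
        """
        w = self.weights or {g: 1.0 for g in GROUPS}
        stack = np.empty((6, 21, 21), dtype=np.int32)
        stack[0] = self.m_noncc.extended_scores()
        stack[1] = self.m_full.extended_scores()
        stack[2] = self.m_cc.extended_scores()
        for k, g in enumerate(GROUPS):
            if mode == "ccalignx" and self.m_group is not None:
                stack[3 + k] = self.m_group[g].extended_scores(w[g])
            else:
                stack[3 + k] = self.m_cc.extended_scores(w[g])
        return stack
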