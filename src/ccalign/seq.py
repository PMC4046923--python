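"""Protein sequences with per-residue coiled-coil annotation.

A coiled coil is an oligomerization motif of two or more intertwined
alpha-helices whose sequence follows a seven-residue (heptad) repeat,
conventionally labelled ``abcdefg``.  Positions ``a`` and ``d`` form the
hydrophobic interface between helices, ``e`` and ``g`` carry the charged
intermediate residues, and ``b``, ``c``, ``f`` face the hydrophilic
outside.  The aligner consumes per-residue coiled-coil probabilities and
heptad registers produced by an external predictor; this module holds the
corresponding domain types and the partition of a protein into
coiled-coil and non-coiled-coil regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: canonical amino-acid order (NCBI matrix convention)
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: heptad registers and the three register groups
REGISTERS = "abcdefg"
NO_REGISTER = "-"
GROUP_OF_REGISTER = {
    "a": "AD", "d": "AD",
    "e": "EG", "g": "EG",
    "b": "BCF", "c": "BCF", "f": "BCF",
}
GROUPS = ("AD", "EG", "BCF")


def encode_sequence(residues: str) -> np.ndarray:
    """Encode residues as integers 0..19; any non-standard letter (X, B, Z,
    U, O ...) maps to 20, which scores via the base matrix's X column."""
    out = np.full(len(residues), 20, dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = AA_INDEX.get(ch, 20)
    return out


@dataclass
class AnnotatedProtein:
    """A protein sequence plus per-residue coiled-coil annotation.

    Parameters
    ----------
    id : str
        Unique protein identifier.
    species : str
        Species tag (used by the reciprocal-best-hit search).
    residues : str
        Upper-case amino-acid string over the 20-letter alphabet; ``X``
        is allowed for unknown residues.
    cc_prob : array-like of float
        Per-residue coiled-coil probability in [0, 1].
    register : array-like of single characters
        Per-residue heptad register in ``a``..``g``, or ``-`` where the
        predictor assigned none.
    """

    id: str
    species: str
    residues: str
    cc_prob: np.ndarray
    register: np.ndarray

    def __post_init__(self) -> None:
        self.cc_prob = np.asarray(self.cc_prob, dtype=float)
        self.register = np.asarray(list(self.register), dtype="<U1") \
            if isinstance(self.register, str) else np.asarray(self.register, dtype="<U1")
        n = len(self.residues)
        if len(self.cc_prob) != n or len(self.register) != n:
            raise ValueError(
                f"{self.id}: residues ({n}), cc_prob ({len(self.cc_prob)}) and "
                f"register ({len(self.register)}) must have equal length"
            )
        if n and (self.cc_prob.min() < 0 or self.cc_prob.max() > 1):
            raise ValueError(f"{self.id}: cc_prob outside [0, 1]")
        bad = set(self.register) - set(REGISTERS) - {NO_REGISTER}
        if bad:
            raise ValueError(f"{self.id}: invalid register labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def cc_mask(self, cutoff: float) -> np.ndarray:
        """Boolean mask of coiled-coil residues (cc_prob >= cutoff)."""
        return self.cc_prob >= cutoff

    def effective_register(self, cutoff: float) -> np.ndarray:
        """Registers with predictor gaps inside coiled-coil runs filled in.

        A coiled-coil residue without a register label inherits the
        register of the nearest register-annotated coiled-coil residue
        (ties broken to the left).  Residues below the cutoff keep ``-``.
        If no coiled-coil residue carries a register the gap remains and
        a warning is logged; such residues count as coiled-coil but join
        no register group.
        """
        mask = self.cc_mask(cutoff)
        reg = np.where(mask, self.register, NO_REGISTER).astype("<U1")
        missing = mask & (reg == NO_REGISTER)
        if not missing.any():
            return reg
        annotated = np.flatnonzero(mask & (reg != NO_REGISTER))
        if annotated.size == 0:
            logger.warning(
                "%s: coiled-coil residues have no register annotation; "
                "they will belong to no register group", self.id,
            )
            return reg
        for i in np.flatnonzero(missing):
            j = annotated[np.argmin(np.abs(annotated - i))]
            left = annotated[np.abs(annotated - i) == abs(j - i)]
            reg[i] = reg[left.min()]  # tie -> left neighbour
        return reg


@dataclass
class RegionPartition:
    """Partition of a protein into coiled-coil and non-coiled-coil regions.

    Intervals are 1-based, closed, disjoint, sorted, and jointly cover
    ``1..length``.
    """

    length: int
    cc_intervals: list[tuple[int, int]]
    noncc_intervals: list[tuple[int, int]]
    group_of: dict[str, str] = field(default_factory=lambda: dict(GROUP_OF_REGISTER))

    def __post_init__(self) -> None:
        covered = sorted(self.cc_intervals + self.noncc_intervals)
        pos = 1
        for s, e in covered:
            if s != pos or e < s:
                raise ValueError("intervals must be disjoint, sorted and cover 1..length")
            pos = e + 1
        if pos != self.length + 1:
            raise ValueError("intervals do not cover 1..length")

    def cc_mask(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for s, e in self.cc_intervals:
            mask[s - 1:e] = True
        return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """1-based closed intervals of True runs in a boolean mask."""
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        out.append((int(idx[s]) + 1, int(idx[e]) + 1))
    return out


def intervals_from_mask(mask: np.ndarray) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(True-runs, False-runs) of a boolean mask as 1-based closed intervals."""
    return _runs(mask), _runs(~mask)


def partition_protein(p: AnnotatedProtein, cutoff: float = 0.8) -> RegionPartition:
    """Split a protein into coiled-coil and non-coiled-coil intervals.

    A residue is coiled-coil iff ``cc_prob >= cutoff`` (inclusive
    comparison, so a residue at exactly the cutoff counts as coiled-coil).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if len(p) == 0:
        raise ValueError("empty protein")
    cc, noncc = intervals_from_mask(p.cc_mask(cutoff))
    return RegionPartition(length=len(p), cc_intervals=cc, noncc_intervals=noncc)


def extract_subsequences(p: AnnotatedProtein, part: RegionPartition,
                         cutoff: float = 0.8) -> dict[str, str]:
    """Concatenated subsequences per region class and register group.

    Returns a dict with keys ``cc``, ``noncc``, ``AD``, ``EG``, ``BCF``.
    Register-group strings collect coiled-coil residues whose (effective)
    register maps to the group; coiled-coil residues without any register
    appear in ``cc`` but in no group.
    """
    if part.length != len(p):
        raise ValueError("partition inconsistent with protein")
    mask = part.cc_mask()
    seq = np.asarray(list(p.residues), dtype="<U1")
    reg = p.effective_register(cutoff)
    out = {
        "cc": "".join(seq[mask]),
        "noncc": "".join(seq[~mask]),
    }
    for group in GROUPS:
        members = [r for r, g in GROUP_OF_REGISTER.items() if g == group]
        gmask = mask & np.isin(reg, members)
        out[group] = "".join(seq[gmask])
    return out
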