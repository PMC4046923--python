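"""All-vs-all proteome search and reciprocal-best-hit orthology calls.

The search runs in two exact stages, mirroring a multi-step
all-against-all alignment: a plain-mode Smith-Waterman-Gotoh pass over
every cross-species pair ranks subjects per query, and the top hits per
query and target species are then re-aligned with the requested
coiled-coil-aware mode.  Both stages are full dynamic programming; the
prescreen only bounds how many pairs receive per-pair compositional
matrix adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import (
    AlignParams,
    align_score,
    bit_score,
    build_matrix_set,
)
from .matrices import ScoreMatrix, blosum62
from .seq import AnnotatedProtein

HIT_COLUMNS = ["query_id", "subject_id", "query_species", "subject_species",
               "bit_score", "raw_score"]

DEFAULT_TOP_N = 50
DEFAULT_BIT_CUTOFF = 30.0


@dataclass
class HitTable:
    """Cross-species alignment hits, truncated to the strongest
    ``top_n`` subjects per (query, subject species)."""

    records: pd.DataFrame
    top_n: int = DEFAULT_TOP_N

    def __post_init__(self) -> None:
        self.records = pd.DataFrame(self.records, columns=HIT_COLUMNS)

    def best_hits(self) -> dict[str, tuple[str, float]]:
        """Per query, the unique best subject and its bit score; queries
        whose best score is tied between subjects are dropped."""
        out: dict[str, tuple[str, float]] = {}
        for qid, grp in self.records.groupby("query_id", sort=False):
            top = grp["bit_score"].max()
            tied = grp[grp["bit_score"] == top]
            if len(tied) == 1:
                row = tied.iloc[0]
                out[qid] = (row["subject_id"], float(top))
        return out


def _truncate(records: list[tuple], top_n: int) -> list[tuple]:
    """Keep the top_n hits by bit score (desc), subject id (asc) for one
    (query, subject-species) bucket."""
    records.sort(key=lambda r: (-r[4], r[1]))
    return records[:top_n]


def all_vs_all(proteomes: list[tuple[str, list[AnnotatedProtein]]],
               params: AlignParams | None = None,
               base: ScoreMatrix | None = None,
               top_n: int = DEFAULT_TOP_N,
               rescreen_n: int | None = None) -> HitTable:
    """Align every protein against every protein of every other species.

    ``proteomes`` is a list of (species, proteins).  For coiled-coil-aware
    modes, a plain-mode pass ranks the subjects of each query first and
    only the strongest ``rescreen_n`` (default ``top_n``) per target
    species are re-aligned with per-pair adjusted matrices.
    """
    params = params or AlignParams()
    base = base or blosum62()
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    seen: set[str] = set()
    for _, prots in proteomes:
        for p in prots:
            if p.id in seen:
                raise ValueError(f"duplicate protein id {p.id}")
            seen.add(p.id)
    lam, K = params.lambda_k
    plain = AlignParams(mode="plain", gap_open=params.gap_open,
                        gap_extend=params.gap_extend, lambda_k=params.lambda_k)
    plain_set = _plain_set(base)
    rescreen_n = rescreen_n if rescreen_n is not None else top_n

    rows: list[tuple] = []
    for qsp, qprots in proteomes:
        for ssp, sprots in proteomes:
            if qsp == ssp:
                continue
            for q in qprots:
                scored: list[tuple] = []
                for s in sprots:
                    raw = align_score(q, s, plain_set, plain)
                    scored.append((q.id, s.id, qsp, ssp,
                                   bit_score(raw, lam, K), raw))
                if params.mode == "plain":
                    rows.extend(_truncate(scored, top_n))
                    continue
                prescreen = _truncate(scored, rescreen_n)
                by_id = {p.id: p for p in sprots}
                rescored: list[tuple] = []
                for rec in prescreen:
                    s = by_id[rec[1]]
                    mset = build_matrix_set(q, s, params, base)
                    raw = align_score(q, s, mset, params)
                    rescored.append((q.id, s.id, qsp, ssp,
                                     bit_score(raw, lam, K), raw))
                rows.extend(_truncate(rescored, top_n))
    return HitTable(records=pd.DataFrame(rows, columns=HIT_COLUMNS),
                    top_n=top_n)


def _plain_set(base: ScoreMatrix):
    from .matrices import MatrixSet

    return MatrixSet(m_cc=base, m_noncc=base, m_full=base)


def reciprocal_best_hits(table: HitTable,
                         bit_cutoff: float = DEFAULT_BIT_CUTOFF) -> set[frozenset]:
    """Reciprocal best hits: x and y (in different species) are an RBH
    pair iff each is the other's unique best hit in the respective
    species and both bit scores reach the cutoff.  Exact bit-score ties
    for a query's best hit disqualify that query (conservative)."""
    df = table.records
    best: dict[tuple[str, str], tuple[str, float]] = {}
    dropped: set[tuple[str, str]] = set()
    for (qid, ssp), grp in df.groupby(["query_id", "subject_species"], sort=False):
        top = grp["bit_score"].max()
        tied = grp[grp["bit_score"] == top]
        if len(tied) > 1:
            dropped.add((qid, ssp))
            continue
        best[(qid, ssp)] = (tied.iloc[0]["subject_id"], float(top))
    species_of = dict(zip(df["query_id"], df["query_species"]))
    out: set[frozenset] = set()
    for (qid, ssp), (sid, qbits) in best.items():
        if qbits < bit_cutoff:
            continue
        qsp = species_of.get(qid)
        back = best.get((sid, qsp))
        if back is None:
            continue
        sid_back, sbits = back
        if sid_back == qid and sbits >= bit_cutoff:
            out.add(frozenset((qid, sid)))
    return out
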