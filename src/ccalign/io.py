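"""Readers and writers for the on-disk formats, plus run configuration.

Formats: FASTA (sequences), "cctsv v1" (per-residue coiled-coil
annotation: protein_id, pos, cc_prob, register; 1-based positions; rows
may be sparse — a missing position means probability 0), outfmt6-like
hit tables, gold ortholog pair tables, homology-group tables, gapless
block alignments with register labels, and a YAML run configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from scipy import stats

from .matrices import Block
from .seq import AnnotatedProtein

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds in one place; defaults follow the published
    settings where stated (coiled-coil probability cutoff 0.8, bit-score
    cutoff 30, coiled-coil protein content threshold 20%, top 50 hits
    per species)."""

    mode: str = "ccalign"
    matrix: str = "BLOSUM62"
    cc_cutoff: float = 0.8
    bit_cutoff: float = 30.0
    cc_content_threshold: float = 0.20
    gap_open: int = 11
    gap_extend: int = 1
    weights_scheme: str = "median"
    bonus: int = 1
    top_n: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def header(self) -> str:
        fields = ",".join(f"{f.name}={getattr(self, f.name)}"
                          for f in dataclasses.fields(self))
        return f"# ccalign config: {fields}"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence).

    Sequences are upper-cased, ``*`` stripped, and the rare letters
    U/O mapped to X (with a warning).  Duplicate ids and empty files are
    errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("*", "")
        if "U" in seq or "O" in seq:
            logger.warning("%s: mapping U/O to X in %s", path, rec.id)
            seq = seq.replace("U", "X").replace("O", "X")
        out.append((rec.id, seq))
    return out


def write_fasta(path, items: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in items:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# cctsv v1
# ---------------------------------------------------------------------------

CCTSV_COLUMNS = ["protein_id", "pos", "cc_prob", "register"]


def write_cc_annotations(path, proteins: list[AnnotatedProtein],
                         config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header() + "\n")
        fh.write("\t".join(CCTSV_COLUMNS) + "\n")
        for p in proteins:
            for i in range(len(p)):
                fh.write(f"{p.id}\t{i + 1}\t{p.cc_prob[i]:g}\t{p.register[i]}\n")


def read_cc_annotations(path) -> dict[str, list[tuple[int, float, str]]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CCTSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[tuple[int, float, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, []).append(
            (int(row.pos), float(row.cc_prob), str(row.register)))
    return out


def load_proteome(fasta_path, cctsv_path, species: str) -> list[AnnotatedProtein]:
    """Combine a FASTA file and its annotation table into annotated
    proteins; positions absent from the table get probability 0 and no
    register."""
    annots = read_cc_annotations(cctsv_path) if cctsv_path else {}
    proteins = []
    for pid, seq in read_fasta(fasta_path):
        prob = np.zeros(len(seq))
        reg = np.full(len(seq), "-", dtype="<U1")
        for pos, p, r in annots.get(pid, []):
            if not 1 <= pos <= len(seq):
                raise ValueError(f"{pid}: annotation position {pos} outside sequence")
            prob[pos - 1] = p
            reg[pos - 1] = r if r in "abcdefg" else "-"
        proteins.append(AnnotatedProtein(id=pid, species=species, residues=seq,
                                         cc_prob=prob, register=reg))
    return proteins


def write_proteome(proteins: list[AnnotatedProtein], fasta_path, cctsv_path,
                   config: RunConfig | None = None) -> None:
    write_fasta(fasta_path, [(p.id, p.residues) for p in proteins])
    write_cc_annotations(cctsv_path, proteins, config)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_gold(path, pairs, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header() + "\n")
        fh.write("id1\tid2\n")
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")


def read_gold(path) -> set[frozenset]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {frozenset((a, b)) for a, b in zip(df["id1"], df["id2"])}


def write_alignments(path, alignments, config: RunConfig | None = None) -> None:
    """Outfmt6-like TSV: qid sid pident length qstart qend sstart send
    raw bits."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header() + "\n")
        fh.write("query_id\tsubject_id\tpident\tlength\tq_start\tq_end\t"
                 "s_start\ts_end\traw_score\tbit_score\n")
        for a in alignments:
            fh.write(f"{a.query_id}\t{a.subject_id}\t{a.pident:.1f}\t{a.length}\t"
                     f"{a.q_start}\t{a.q_end}\t{a.s_start}\t{a.s_end}\t"
                     f"{a.raw_score}\t{a.bit_score:.2f}\n")


def write_hit_table(path, table, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header() + "\n")
        table.records.to_csv(fh, sep="\t", index=False)


def read_hit_table(path):
    from .search import HitTable

    return HitTable(records=pd.read_csv(path, sep="\t", comment="#"))


def write_groups(path, groups: list[set], species_of: dict[str, str] | None = None,
                 config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header() + "\n")
        fh.write("group_id\tprotein_id\tspecies\n")
        for gi, group in enumerate(sorted(groups, key=lambda g: sorted(g)[0])):
            for pid in sorted(group):
                sp = species_of.get(pid, "") if species_of else ""
                fh.write(f"OG{gi:05d}\t{pid}\t{sp}\n")


def read_groups(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.group_id, set()).add(row.protein_id)
    return out


# ---------------------------------------------------------------------------
# block alignments (plain text: header, gapless rows, register line)
# ---------------------------------------------------------------------------

def read_blocks(path) -> list[Block]:
    blocks: list[Block] = []
    name = None
    rows: list[str] = []
    registers = None

    def flush():
        if name is not None:
            if registers is None:
                raise ValueError(f"block {name}: missing register line")
            blocks.append(Block(name=name, sequences=list(rows), registers=registers))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                rows = []
                registers = None
            elif line.startswith("="):
                registers = line[1:].strip()
            else:
                rows.append(line)
    flush()
    if not blocks:
        raise ValueError(f"{path}: no blocks found")
    return blocks


def write_blocks(path, blocks: list[Block]) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f">{b.name}\n")
            for row in b.sequences:
                fh.write(row + "\n")
            fh.write("=" + b.registers + "\n")


# ---------------------------------------------------------------------------
# protein categorization helpers
# ---------------------------------------------------------------------------

def cc_content(p: AnnotatedProtein, cutoff: float = 0.8) -> float:
    """Fraction of residues predicted coiled-coil at the cutoff.
    Proteins at or above 20% are conventionally categorized as
    coiled-coil (scaffold-like) proteins."""
    if len(p) == 0:
        return 0.0
    return float(np.mean(p.cc_mask(cutoff)))


def enrichment_test(k: int, n: int, p0: float) -> float:
    """One-sided binomial tail P(X >= k), X ~ Binomial(n, p0): the
    large-background limit of the one-sided Fisher exact test for
    enrichment of a category among n draws."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))
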