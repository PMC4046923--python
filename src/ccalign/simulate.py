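"""Seeded generator of synthetic coiled-coil protein families.

Each family is an ancestral protein with a fixed coiled-coil
architecture (flank - domain - spacer - ... - domain - flank) whose
coiled-coil residues cycle through the heptad registers and are drawn
from register-group frequency tables: the a/d interface is
hydrophobic-enriched, e/g carries charged residues, b/c/f hydrophilic
ones, and non-coiled-coil residues follow a generic background.  Two
descendant sequences per family are produced by independent per-site
substitution (register-conditional inside coiled coils), one per
species; decoys share the coiled-coil architecture and register-level
composition but are ancestrally unrelated, which is exactly what makes
them attract alignments under a generic substitution matrix.

Everything is reproducible from the seed; no claim of biological
realism is attached to the frequency tables beyond the qualitative
register structure described above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmark import GoldStandard
from .matrices import Block
from .seq import AA_ORDER, GROUP_OF_REGISTER, REGISTERS, AnnotatedProtein

#: hydrophobic residues enriched at heptad a/d positions
HYDROPHOBIC = set("LIVMAF")

CC_PROB_IN = 0.95
CC_PROB_OUT = 0.05


def _table(d: dict[str, float]) -> np.ndarray:
    t = np.zeros(20)
    for aa, f in d.items():
        t[AA_ORDER.index(aa)] = f
    if abs(t.sum() - 1.0) > 1e-9:
        raise ValueError("frequency table must sum to 1")
    return t


#: register-group residue frequencies (hydrophobic mass at a/d = 0.80)
DEFAULT_REGISTER_TABLES = {
    "AD": _table({"L": 0.34, "I": 0.14, "V": 0.11, "M": 0.05, "A": 0.11,
                  "F": 0.05, "K": 0.05, "E": 0.05, "N": 0.03, "Q": 0.03,
                  "S": 0.02, "R": 0.02}),
    "EG": _table({"E": 0.22, "K": 0.20, "R": 0.12, "Q": 0.10, "D": 0.08,
                  "N": 0.05, "A": 0.06, "L": 0.05, "S": 0.05, "T": 0.04,
                  "I": 0.03}),
    "BCF": _table({"S": 0.12, "T": 0.10, "N": 0.10, "D": 0.10, "E": 0.10,
                   "Q": 0.08, "K": 0.08, "R": 0.06, "G": 0.06, "A": 0.06,
                   "P": 0.04, "H": 0.04, "L": 0.03, "V": 0.03}),
}

#: generic background (approximate database amino-acid frequencies)
DEFAULT_BACKGROUND = _table({
    "A": 0.083, "R": 0.056, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.040, "E": 0.068, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.066})


@dataclass
class FamilySpec:
    """Study conditions for the synthetic families."""

    n_families: int = 200
    cc_fraction: float = 0.30
    n_cc_domains: int = 2
    domain_length: tuple[int, int] = (21, 42)
    linker_length: tuple[int, int] = (30, 70)
    divergence: float = 0.55
    decoys_per_family: int = 3
    indel_rate: float = 0.0
    seed: int = 42
    #: relative substitution rates per register group: the hydrophobic
    #: interface is the most conserved (it carries the most phylogenetic
    #: signal), the hydrophilic outside the least; weighted by register
    #: multiplicity (2:2:3) these average to 1, so ``divergence`` stays
    #: the mean coiled-coil rate
    group_rate_scale: dict = field(default_factory=lambda: {
        "AD": 0.7, "EG": 1.0, "BCF": 1.2, "-": 1.0})
    register_tables: dict = field(default_factory=lambda: dict(DEFAULT_REGISTER_TABLES))
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        if self.domain_length[0] < 7 or self.linker_length[0] < 7:
            raise ValueError("all lengths must cover at least one heptad")
        if self.n_cc_domains < 1 or self.n_families < 1:
            raise ValueError("need at least one domain and one family")


@dataclass
class SimulatedFamilies:
    proteomes: dict[str, list[AnnotatedProtein]]
    gold: GoldStandard
    spec: FamilySpec


def _architecture(spec: FamilySpec, rng: np.random.Generator):
    """Domain and flank lengths; flank budget is scaled so the realized
    coiled-coil fraction matches the target."""
    domains = rng.integers(spec.domain_length[0], spec.domain_length[1] + 1,
                           size=spec.n_cc_domains)
    cc_total = int(domains.sum())
    budget = int(round(cc_total * (1.0 - spec.cc_fraction) / spec.cc_fraction))
    raw = rng.integers(spec.linker_length[0], spec.linker_length[1] + 1,
                       size=spec.n_cc_domains + 1).astype(float)
    flanks = np.maximum(1, np.round(raw / raw.sum() * budget).astype(int))
    return domains, flanks


def _sample_site_distributions(domains, flanks, spec: FamilySpec):
    """Per-site register label and sampling distribution index."""
    regs: list[str] = []
    for k, d in enumerate(domains):
        regs.append("-" * flanks[k])
        regs.append("".join(REGISTERS[i % 7] for i in range(d)))
    regs.append("-" * flanks[-1])
    return "".join(regs)


def _draw_sequence(regs: str, spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    codes = np.empty(len(regs), dtype=np.int64)
    for i, r in enumerate(regs):
        if r == "-":
            codes[i] = rng.choice(20, p=spec.background)
        else:
            codes[i] = rng.choice(20, p=spec.register_tables[GROUP_OF_REGISTER[r]])
    return codes


def _exchange_kernels(spec: FamilySpec) -> dict[str, np.ndarray]:
    """Conditional substitution kernels P(b | a), one per register group
    plus the non-coiled-coil background.

    Substitutions are conservative, following the BLOSUM62 exchange
    preferences, reweighted towards the register-group composition
    inside coiled coils: P(b | a) proportional to q62(a, b) * t(b) /
    bg62(b), where t is the group table.  Pure resampling from the
    composition table would leave substituted sites carrying no signal
    beyond composition — exactly the similarity compositional
    adjustment is built to discount — which real homologs do not do.
    """
    from .matrices import blosum62

    base = blosum62()
    q, bg = base.joint_q, base.bg_row
    kernels: dict[str, np.ndarray] = {}
    tables = dict(spec.register_tables)
    tables["-"] = spec.background
    for key, t in tables.items():
        K = q * (t / bg)[None, :]
        np.fill_diagonal(K, 0.0)  # a substituted site changes its residue
        K /= K.sum(axis=1, keepdims=True)
        kernels[key] = K
    return kernels


def _mutate(codes: np.ndarray, regs: str, spec: FamilySpec,
            rng: np.random.Generator, kernels: dict[str, np.ndarray]) -> np.ndarray:
    out = codes.copy()
    rates = np.array([
        min(1.0, spec.divergence * spec.group_rate_scale[
            GROUP_OF_REGISTER.get(r, "-")]) for r in regs])
    hit = rng.random(len(codes)) < rates
    for i in np.flatnonzero(hit):
        r = regs[i]
        K = kernels["-"] if r == "-" else kernels[GROUP_OF_REGISTER[r]]
        out[i] = rng.choice(20, p=K[codes[i]])
    return out


def _apply_indels(codes: np.ndarray, regs: str, prob: np.ndarray,
                  spec: FamilySpec, rng: np.random.Generator):
    if spec.indel_rate <= 0:
        return codes, regs, prob
    keep = rng.random(len(codes)) >= spec.indel_rate / 2
    insert = rng.random(len(codes)) < spec.indel_rate / 2
    out_c, out_r, out_p = [], [], []
    for i in range(len(codes)):
        if keep[i]:
            out_c.append(codes[i]); out_r.append(regs[i]); out_p.append(prob[i])
        if insert[i]:
            out_c.append(rng.choice(20, p=spec.background))
            out_r.append("-"); out_p.append(CC_PROB_OUT)
    return np.array(out_c), "".join(out_r), np.array(out_p)


def _protein(pid: str, species: str, codes: np.ndarray, regs: str,
             prob: np.ndarray) -> AnnotatedProtein:
    seq = "".join(AA_ORDER[c] for c in codes)
    return AnnotatedProtein(id=pid, species=species, residues=seq,
                            cc_prob=prob, register=np.array(list(regs)))


def generate(spec: FamilySpec | None = None) -> SimulatedFamilies:
    """Generate two annotated proteomes plus the gold ortholog pairs.

    Per family: one ancestor, two descendants (one per species, linked
    in the gold standard) and ``decoys_per_family`` unrelated decoys
    with the same kind of architecture, alternated between the two
    species.  Annotation probabilities are 0.95 inside coiled-coil
    domains and 0.05 outside.
    """
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    kernels = _exchange_kernels(spec)
    species = ("spA", "spB")
    proteomes: dict[str, list[AnnotatedProtein]] = {sp: [] for sp in species}
    gold_pairs = []
    decoy_counter = 0
    for fam in range(spec.n_families):
        domains, flanks = _architecture(spec, rng)
        regs = _sample_site_distributions(domains, flanks, spec)
        prob = np.where(np.array(list(regs)) == "-", CC_PROB_OUT, CC_PROB_IN)
        ancestor = _draw_sequence(regs, spec, rng)
        ids = (f"f{fam:04d}_spA", f"f{fam:04d}_spB")
        for sp, pid in zip(species, ids):
            codes = _mutate(ancestor, regs, spec, rng, kernels)
            c, r, pr = _apply_indels(codes, regs, prob, spec, rng)
            proteomes[sp].append(_protein(pid, sp, c, r, pr))
        gold_pairs.append(ids)
        for _ in range(spec.decoys_per_family):
            sp = species[decoy_counter % 2]
            decoy_counter += 1
            d_domains, d_flanks = _architecture(spec, rng)
            d_regs = _sample_site_distributions(d_domains, d_flanks, spec)
            d_prob = np.where(np.array(list(d_regs)) == "-", CC_PROB_OUT, CC_PROB_IN)
            d_codes = _draw_sequence(d_regs, spec, rng)
            proteomes[sp].append(
                _protein(f"d{decoy_counter:04d}_{sp}", sp, d_codes, d_regs, d_prob))
    return SimulatedFamilies(proteomes=proteomes,
                             gold=GoldStandard.from_pairs(gold_pairs),
                             spec=spec)


def make_register_blocks(n_blocks: int = 12, n_seqs: int = 8, width: int = 28,
                         seed: int = 7,
                         conservation: dict[str, float] | None = None) -> list[Block]:
    """Blocks of aligned coiled-coil segments with register-labelled
    columns, for estimating register-group matrices and entropies.

    Column conservation differs by register group (interface most
    conserved), which reproduces the qualitative entropy ordering
    AD > EG > BCF observed on curated conserved blocks.
    """
    cons = conservation or {"AD": 0.70, "EG": 0.55, "BCF": 0.42}
    rng = np.random.default_rng(seed)
    blocks = []
    for b in range(n_blocks):
        start = rng.integers(0, 7)
        regs = "".join(REGISTERS[(start + i) % 7] for i in range(width))
        rows = []
        consensus = [rng.choice(20, p=DEFAULT_REGISTER_TABLES[GROUP_OF_REGISTER[r]])
                     for r in regs]
        for _ in range(n_seqs):
            row = []
            for c, r in zip(consensus, regs):
                g = GROUP_OF_REGISTER[r]
                if rng.random() < cons[g]:
                    row.append(AA_ORDER[c])
                else:
                    row.append(AA_ORDER[rng.choice(20, p=DEFAULT_REGISTER_TABLES[g])])
            rows.append("".join(row))
        blocks.append(Block(name=f"synthetic_block_{b:02d}", sequences=rows,
                            registers=regs))
    return blocks
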