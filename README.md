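# ccalign

Coiled-coil-aware pairwise protein alignment and orthology detection.

Coiled-coil domains follow a seven-residue heptad repeat
(`abcdefg`, hydrophobic interface at `a`/`d`, charged residues at
`e`/`g`, hydrophilic outside at `b`/`c`/`f`).  Because *every*
coiled coil shares this biased periodic composition, generic
substitution matrices such as BLOSUM62 systematically overestimate
the similarity of unrelated coiled-coil proteins, and similarity
searches either call false homologs or — when coiled coils are
masked — miss true ones.  This matters wherever coiled-coil
proteins dominate, e.g. among the scaffold proteins of the
centrosome.

`ccalign` implements a refined local alignment for such proteins:

* **Compositional matrix adjustment with fixed relative entropy.**
  For each protein pair, substitution matrices are re-derived so
  that the implied joint distribution Q minimizes KL(Q‖Q₀) subject
  to the amino-acid compositions of the two regions as marginals and
  the base matrix's relative entropy
  H = Σ q_ab log₂(q_ab/(p_a p_b)) (0.70 bits for BLOSUM62) held
  fixed — separately for the coiled-coil sections, the
  non-coiled-coil sections, and the full-length pair.
* **Region-switched Smith–Waterman–Gotoh.**  A full local dynamic
  program (affine gaps 11/1) selects the matrix per residue pair by
  coiled-coil state; in register-aware mode (`ccalignx`) the heptad
  register groups a/d, e/g, b/c/f get their own adjusted matrices,
  scores are weighted by each group's phylogenetic signal
  (entropy / median entropy), and aligned pairs with matching
  registers earn a bonus.
* **Orthology machinery.**  All-vs-all search with top-50 re-scoring
  per species, reciprocal-best-hit calling (bit score ≥ 30, unique
  best both ways), 2-of-3 method voting, betweenness-centrality
  pruning of spurious homology links, and diameter-capped merging of
  orthologous groups.
* **Benchmarking.**  Artificial high-coiled-coil proteins (excised
  coiled-coil domains plus linkers of 10–100 residues), best-hit FDR
  curves, and recall at 5% FDR per method.
* **Synthetic data.**  A seeded generator of coiled-coil protein
  families (register-structured composition, conservative
  substitution kernel, architecture-matched decoys) so the whole
  pipeline is testable with no external data.

## Worked example

Align one simulated protein against its true ortholog and against a
decoy that shares the same coiled-coil architecture but is
unrelated:

```python
from ccalign import AlignParams, align_pair, generate, FamilySpec

sim = generate(FamilySpec(n_families=2, decoys_per_family=1, seed=7))
q = sim.proteomes["spA"][0]   # family 0, species A descendant
t = sim.proteomes["spB"][0]   # its true ortholog
d = sim.proteomes["spB"][2]   # architecture-matched decoy

for mode in ("plain", "ccalign", "ccalignx"):
    params = AlignParams(mode=mode, adjust=mode != "plain")
    a_true = align_pair(q, t, params)
    a_decoy = align_pair(q, d, params)
    print(f"{mode:9s} true {a_true.bit_score:6.1f} bits   "
          f"decoy {a_decoy.bit_score:6.1f} bits   "
          f"margin {a_true.bit_score - a_decoy.bit_score:5.1f}")
```

prints

```
plain     true   76.3 bits   decoy   19.2 bits   margin  57.0
ccalign   true   64.7 bits   decoy   14.2 bits   margin  50.5
ccalignx  true   82.4 bits   decoy   20.0 bits   margin  62.4
```

The true ortholog wins under every mode; the register-aware mode
widens the margin because aligned residues with matching heptad
registers are rewarded, a signal the decoy cannot imitate
consistently.  `bit_score = (λ·raw − ln K)/ln 2` with the gapped
BLOSUM62 parameters λ = 0.267, K = 0.041.

The same functionality is exposed on the command line:

```sh
ccalign simulate --seed 42 --out sim/
ccalign search --proteome spA=sim/spA.fa:sim/spA.cctsv \
               --proteome spB=sim/spB.fa:sim/spB.cctsv \
               --mode ccalignx --out hits.tsv
ccalign rbh --hits hits.tsv --bit-cutoff 30 --out orthologs.tsv
ccalign bench --seed 42 --out bench.tsv
```

Per-residue coiled-coil annotations are read from a TSV
(`protein_id, pos, cc_prob, register`, 1-based, sparse rows allowed)
as exported from an external coiled-coil predictor; the package does
not predict coiled coils itself.

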