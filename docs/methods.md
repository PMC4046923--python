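# Methods

## The problem

Coiled-coil domains follow the seven-residue heptad repeat
`abcdefg`, with hydrophobic residues at `a`/`d` (the helix–helix
interface), charged residues at `e`/`g` and hydrophilic residues at
`b`/`c`/`f`.  Because every coiled coil shares this biased, periodic
composition, a generic substitution matrix such as BLOSUM62 awards
unrelated coiled-coil proteins large alignment scores, and
similarity searches either report false homologs or — if coiled
coils are masked — miss true ones.  This package implements a
coiled-coil-aware local alignment and the orthology machinery built
on top of it.

## Alignment model

Every protein carries per-residue coiled-coil probabilities and
heptad registers from an external predictor (the package never
predicts coiled coils itself).  A residue is treated as coiled-coil
when its probability is at or above the cutoff (default 0.8; the
comparison is inclusive, so a residue exactly at the cutoff counts).
A predictor gap inside a coiled-coil run inherits the register of
the nearest annotated coiled-coil residue, ties resolved leftwards;
if no register exists anywhere in the protein the residues stay
group-less and score through the generic coiled-coil matrix.

For a pair of proteins, the coiled-coil and non-coiled-coil sections
of each are concatenated and compositionally adjusted substitution
matrices are computed for the coiled-coil pair, the non-coiled-coil
pair and the full-length pair.  A standard Smith–Waterman–Gotoh
local alignment then runs over the full sequences, but the
substitution matrix is selected per residue pair:

* both residues coiled-coil → the coiled-coil matrix (`ccalign`
  mode) or the register-group matrix of the more confidently
  predicted residue (`ccalignx` mode; the query wins probability
  ties);
* neither → the non-coiled-coil matrix;
* mixed → the full-length matrix.

In `ccalignx` mode the coiled-coil residues are further split into
the register groups a/d, e/g and b/c/f, with one adjusted matrix
per group, and a bonus (default 1 half-bit, configurable) is added
for every aligned pair whose predicted registers agree.  The bonus
is per aligned pair, not per matched segment.

Register groups differ in how much phylogenetic signal they carry
(the interface is most informative).  Group scores are therefore
weighted: the group relative entropies are divided by their median
(default scheme; a BLOSUM62-normalized scheme and `off` are
available), and the weight multiplies the unrounded log-odds of the
group's matrix before integer rounding, so the dynamic programming
stays integer-only.  Weights are applied in both coiled-coil-aware
modes.  The default group entropies are 0.45 (a/d), 0.32 (e/g) and
0.28 (b/c/f) bits, giving median-normalized weights 1.41/1.00/0.88;
`build_register_matrices` re-estimates entropies from
register-labelled gapless blocks (BLOSUM-style clustered pair
counting) when block data are available.

Gap costs follow the BLAST protein defaults, open 11 / extend 1,
with the BLAST convention that a gap of length g costs
`open + g·extend`.  Tie-breaks are fixed for determinism: diagonal
over up over left in the traceback, first maximum in row-major
order for the alignment end, and lexicographically smallest subject
id between equal-scoring hits.  Raw scores convert to bit scores as
`(λ·raw − ln K)/ln 2` with the gapped BLOSUM62 11/1 parameters
λ = 0.267, K = 0.041.

Unknown residues (X, or any non-standard letter) are excluded from
composition estimation and score through the base matrix's X
column, unadjusted and unweighted; they are treated as
non-coiled-coil when partitioning.

## Compositional adjustment

The adjusted joint distribution Q minimizes KL(Q‖Q₀) over the base
matrix's joint distribution Q₀ subject to (i) row marginals equal
to the query-region composition, (ii) column marginals equal to the
subject-region composition, and (iii) relative entropy
D(Q‖c₁⊗c₂) equal to the base matrix's (0.70 bits for BLOSUM62) —
the matrix keeps its information content per aligned pair while
matching the observed compositions.  The stationarity conditions
give `q_ab ∝ [q₀_ab (c₁_a c₂_b)^ν]^{1/(1+ν)} e^{A_a+B_b}`: for a
fixed entropy multiplier ν the problem is a Sinkhorn matrix
scaling, and ν is a one-dimensional root of the achieved entropy,
monotone decreasing, solved by bracketing plus Illinois regula
falsi (convergence 1e-10 on the entropy, 1e-12 on the marginals,
warm-started between ν evaluations).  The multiplicative form keeps
every entry positive, so no clamping is needed.  If bracketing
fails (an unreachable entropy target under extreme compositions)
the base matrix is returned flagged unadjusted.

Compositions are pseudocounted with mass 20 distributed according
to the base background (one pseudo-observation per amino acid),
which keeps compositions strictly positive.  Regions shorter than
20 residues re-use the full-length compositions (register groups
fall back to the generic coiled-coil matrix instead), since tiny
samples make adjustment unstable without adding signal.

The shipped BLOSUM62 data deserve a note: the widely published
4-decimal target-frequency table is not exactly consistent with the
canonical integer scores under strict half-bit rounding (the
integers were rounded from higher-precision counts).  The shipped
table is that table minimally refined — the largest change is
4.6 × 10⁻⁵, inside the 4-dp rounding precision — so that scores,
marginals and the 0.70-bit entropy are exactly self-consistent.

## Search, voting, pruning, merging

The all-vs-all search runs in multiple exact stages: a plain-mode
pass over every cross-species pair ranks subjects, and the top 50
per query and target species are re-aligned with per-pair adjusted
matrices.  Both stages are full dynamic programming; the prescreen
only bounds how many pairs receive matrix adjustment.  Reciprocal
best hits require each protein to be the other's unique best hit
(exact bit-score ties disqualify, conservatively) with both bit
scores at or above 30.

Three methods' homolog calls are combined by 2-of-3 voting.  Within
each resulting group the top-betweenness protein (if its centrality
exceeds twice the group median) is tentatively removed, one at a
time; a split into at least two sub-groups of size two or more is
accepted — the removed protein joins the sub-group it shares most
edges with — otherwise the protein is restored.  Orthologous groups
are finally merged in decreasing score order (a stricter threshold
applies when species sets overlap, to avoid merging paralogs),
skipping any merge that would push a cluster's group-graph diameter
beyond four edges.

## The synthetic generator

The generator emulates ortholog detection among coiled-coil
proteins at desk scale.  Each family has an ancestor with a fixed
architecture (two coiled-coil domains of 21–42 residues inside
flanks scaled to a 30% coiled-coil fraction, overall length around
200), registers cycling `a`–`g`, coiled-coil residues drawn from
register-group tables (a/d carries 0.80 total mass on hydrophobic
residues, e/g is charge-enriched, b/c/f hydrophilic) and the rest
from a generic background.  Two descendants (one per species) arise
by independent per-site substitution at a mean coiled-coil rate of
0.55; a substituted site changes its residue, drawn from a
conservative exchange kernel `P(b|a) ∝ q62(a,b)·t(b)/bg(b)`
(BLOSUM62 exchange preferences reweighted to the local
register-group or background table).  Substitution rates are
register-conditional — interface 0.7×, intermediate 1.0×, outside
1.2× the nominal rate, averaging to 1 over the heptad — mirroring
the observation that interface residues carry the most phylogenetic
signal (group entropies 0.45 > 0.32 > 0.28 bits).  The conservative
kernel matters: if substituted sites were resampled independently
from the composition tables, homologs would carry no signal beyond
composition — exactly what compositional adjustment discounts — and
no composition-aware method could beat a fixed matrix.  Likewise,
uniform per-register conservation would contradict the measured
register informativeness that motivates register weighting.  Decoys share the architecture and register composition but
are drawn independently, which is what makes them attract
alignments under an unadjusted matrix.  Annotation probabilities
are 0.95 inside domains and 0.05 outside.  Everything derives from
one seeded RNG stream (default seed 42); an off-by-default indel
mode adds insertions/deletions at a configurable rate.

What the generator does not emulate: real length and domain-count
distributions (centrosomal coiled-coil proteins are often thousands
of residues), predictor noise in probabilities and registers,
indels (by default), paralogy, and multi-species phylogeny.
Passing benchmarks on these fixtures therefore demonstrate the
machinery's correctness and the qualitative method ordering, not
field performance on real proteomes.

## Benchmark

Artificial high-coiled-coil proteins are built by excising every
coiled-coil interval together with a flanking linker (windows
merged when they overlap) and concatenating the windows; sweeping
linker lengths {10, 25, 50, 100} trades away homologous
non-repeat sequence and makes the task harder at the short end.
With the default flank lengths the 50- and 100-residue panels are
close to the intact proteins; the sizes were chosen so a full sweep
(200 families, 500 subjects per query, three methods, four linkers)
completes in minutes on one CPU.  For each query the best hit
among the other species' proteins is correct iff it is an annotated
ortholog; sweeping a bit-score threshold yields an FDR curve, and
the reported recall is read at the loosest threshold with FDR ≤ 5%
among points with at least ten predictions (matching the
convention of suppressing curve points with fewer than ten
predictions).  Recall is reported against both the gold-pair and
the gold-bearing-query denominator (identical for one-to-one
families).

## Numerical and degenerate-input choices

* Score scale fixed at half-bits everywhere so base and adjusted
  matrices are interchangeable inside one alignment.
* Empty alignments (no positive-scoring pair, or all-X sequences)
  return raw score 0 with empty coordinates.
* `compute_composition` on an empty region returns the background;
  a zero pseudocount is allowed but produces degenerate
  compositions that the adjustment solver rejects.
* Register matrices built from blocks use single-linkage clustering
  at 62% identity with 1/cluster-size sequence weights, pair counts
  between clusters only, and a pseudocount mass of 40 pairs spread
  by the observed marginals (floored by a uniform share); groups
  with fewer than 30 weighted pairs raise an error.
* `merge_groups` processes ties in lexicographic group-id order, so
  the output is independent of input order for distinct scores.

## Known limitations

* Karlin–Altschul parameters are fixed at the gapped BLOSUM62 11/1
  values rather than re-estimated per adjusted matrix; bit scores
  across pairs are therefore comparable only to the extent the
  entropy constraint keeps the scale stable (which is its purpose).
* The betweenness threshold (top node above twice the component
  median) is a heuristic; the published procedure defines the
  split-accept/restore logic but no numeric cutoff.
* E-values are out of scope; only bit scores are reported.
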