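# Methods

This note records the models, defaults, and numerical choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Sequence identity and family filtering

Identity between two proteins is computed from one optimal global
(Needleman–Wunsch) alignment under BLOSUM62 with affine gaps (open 11,
extend 1, so a gap of length k costs 11 + (k−1)); 'X' is rescored to 0
against every residue so unknowns neither attract nor repel. The identity
value is identical residues divided by aligned columns after trimming
terminal gap columns, which keeps a short fragment from looking spuriously
divergent. Among co-optimal alignments the dynamic program's first
traceback is used; it is deterministic for a given input, and the unit
suite checks the resulting identity against an independently written
affine-gap DP and, on tiny strings, exhaustive alignment enumeration.

Filtering keeps members whose identity to the designated target lies in
[`min_identity`, `max_identity`] (defaults 0.45 and 0.95 — close enough to
be informative about the target's history, distant enough not to be
redundant) and whose length is at least `min_length_fraction` (default
0.80) of the target length ("truncated" otherwise). The band edges are
inclusive. The target itself is always kept, and filtering is idempotent.

## Substitution models, likelihood, and ancestral reconstruction

Two reversible 20-state models ship with the package: the WAG empirical
matrix (default) and a uniform Poisson model. A model is exchangeabilities
S plus equilibrium frequencies π; Q_ij = S_ij π_j off-diagonal, diagonal
set so rows sum to zero, rescaled so −Σ π_i Q_ii = 1 (branch lengths are
expected substitutions per site). Transition matrices come from the
symmetric eigendecomposition of diag(√π) Q diag(1/√π), exact for
reversible Q; rows of P(t) sum to 1 within 1e−9 for t from 0 to 10.

Trees are built by neighbor joining on pairwise distances (p-distance =
mismatches over shared ungapped columns; Poisson correction
d = −ln(1 − p) with p capped at 0.95 to stay finite). The NJ
implementation is the standard Studier–Keppler algorithm with a
deterministic lowest-index tie-break; a negative branch length from the NJ
length formula is clamped to zero with the deficit moved to its sibling so
the pair's summed length is preserved. On additive matrices the generating
topology and branch lengths are recovered exactly (property-tested on
random 5–8-taxon trees). An externally built Newick tree can be supplied
instead.

The alignment log-likelihood uses Felsenstein pruning with per-node,
per-column rescaling; gaps and 'X' are missing data (all-ones partials).
Marginal ancestral posteriors come from a second, pre-order pass: the
posterior at a node is proportional to the product of partial likelihoods
from all incident subtrees, with π entering at the root; for reversible
models the result is root-invariant (tested by rerooting). The MAP state
per column is the posterior argmax with alphabetical tie-breaking (the
state order is alphabetical, so argmax does this) and a tie flag. Whether
an ancestor possesses a residue at a column gapped in some leaves is
decided by Fitch parsimony on a binary present/absent character with ties
resolved toward "present" — parsimony rather than likelihood because
indels are not part of the substitution model.

Internal nodes are labeled N1..Nk in preorder after midpoint rooting.
Midpoint rooting is implemented directly (tree diameter by double
traversal, then an edge split) so the degenerate case where the midpoint
falls exactly on an existing node — guaranteed for ultrametric trees — is
handled cleanly.

Node ranking against the target reports identity of the node's MAP
sequence to the target over shared present columns and the fraction of
user-supplied active-site columns where the MAP state equals the target
state, sorted by conservation then identity (configurable). Ranking is
exposed rather than a hard-coded node choice because the right ancestor
depends on the family at hand; an empty active-site set warns and reports
conservation 1.0 by convention.

Branch lengths are used as produced by NJ; per-branch likelihood
re-optimization is deliberately out of scope for the default path, as are
topology search, model selection, and among-site rate heterogeneity.

## Structure parsing and shell selection

Only ATOM records are read (first MODEL, altloc blank or 'A', HETATM
ignored); a malformed ATOM record raises with its line number. Structure
residues are mapped to the target sequence by global alignment of the
structure-derived sequence — not by trusting author numbering, which
deposited files frequently offset — and the mapping refuses to proceed
below 30 % alignment identity. The distance from the catalytic anchor
defaults to the minimum over heavy-atom pairs, since "within 15 Å of the
catalytic histidine" is atom-level language and side chains matter;
CA-only and CB (CA fallback for glycine) modes are selectable. The shell
is all mapped positions within the cutoff, anchor included at distance 0.

Candidate substitutions are emitted where the chosen node's MAP state is
present, differs from the target residue, and has posterior probability at
least 0.5 (configurable floor; below that the reconstruction is too
uncertain to spend library diversity on). All eligible candidates are
reported; final curation is the user's.

## Library design and composition model

Mutant codons minimize nucleotide Hamming distance to the wild-type codon
(ties broken lexicographically A<C<G<T), and each oligo is the mutant
codon with 15-nt flanks (truncated with a warning at gene ends). The bench
reassembly protocol (fragmentation, doped oligos, primerless reassembly)
is abstracted as **independent per-position incorporation**: every
designed position mutates with probability p = target_mean / n_positions
(uniform, since per-oligo stoichiometries are not modeled), and positions
with several ancestral alternatives split p uniformly. The default target
mean is 4 mutations per variant, the midpoint of a 3–5 design window.
Mutation counts are therefore Binomial(n_positions, p), verified by
chi-square at 100 000 simulated variants. Linkage between nearby positions
sharing a fragment is a real effect this model deliberately ignores; it
would fatten the tails of the count distribution without moving its mean.

## Screen analysis

Initial rates are OLS slopes over an automatically chosen early window:
the longest prefix of at least 3 time points whose linear fit keeps
R² ≥ 0.95 (minimal prefix if none qualifies). This excludes
substrate-exhaustion plateaus; note that a single plateau point can
survive the R² gate on gently saturating curves, so slopes are accurate to
a few percent only when the linear phase dominates the sampled window.
Folds are normalized per plate — fold = (slope − mean blank)/(mean WT −
mean blank) — never pooled across plates; a plate whose WT does not rise
above blank is invalid. Hits are folds ≥ 2 (inclusive). Rescreens are
verified by a one-sided Welch t-test of variant replicates against WT
replicates (α = 0.05) plus the mean-fold threshold; two zero-variance
groups with equal means give p = 1 by convention. Z′-factor is reported
per plate as QC.

## Michaelis–Menten fitting

Rates from HPLC peaks assume equal detector response for substrate and
product (configurable factor): converted fraction f = P/(P+S), rate
v = f·[S]_total/t, warning above f = 0.3 (leaving the initial-rate
regime). Fits minimize squared error of v = V_max[S]/(K_M+[S]) in
(log V_max, log K_M) — positivity for free — by Levenberg–Marquardt with
start values V_max⁰ = max v, K_M⁰ = the [S] nearest half-maximal rate, and
a small K_M restart grid (×0.3, ×1, ×3, ×10) against local minima.
Standard errors come from the Jacobian at the optimum (delta method back
to the natural scale); K_M above 10× the largest [S] warns "poorly
constrained". k_cat = V_max/E₀ (E₀ default 0.3 µM, the assay
concentration the comparative table assumes) and efficiency k_cat/K_M in
s⁻¹M⁻¹ hold exactly in every output row. The comparative table reports
percent-of-WT per peptide (WT = 100) with report rounding (k_cat 4
decimals, K_M 2, efficiency and percents to integers) alongside raw
floats; `efficiency_consistency` flags externally quoted efficiency cells
that disagree with their own k_cat and K_M instead of reproducing them.

## Synthetic data: what it emulates, what it does not

`simulate_family` draws a root from π and evolves it down each branch by
sampling from P(t), recording the true sequence at every internal node
(labels match the reconstruction module's scheme by construction). There
are no indels, so the simulated family is its own alignment — real
sirtuin families are not, and alignment error is therefore outside what
passing tests demonstrate. The default fixture (12 taxa, 60 residues, WAG,
root-to-tip depth 0.25 substitutions/site) is small enough for exhaustive
oracles yet deep enough that reconstruction is non-trivial.

`make_toy_structure` places CA atoms on an ideal helix (rise 1.5 Å/residue,
100°/turn, radius 2.3 Å) or an extended chain (3.8 Å spacing), rounds
coordinates to PDB precision, and emits the matching ground-truth distance
matrix. It has no side chains, so it exercises the CA distance mode;
min-heavy-atom behavior is tested on hand-built multi-atom fixtures.

`simulate_plate` writes linear fluorescence time courses (5-minute
sampling over 30 minutes) with Gaussian noise proportional to signal;
plate-reader drift, edge effects, and liquid-handling artifacts are not
modeled. `simulate_mm` applies multiplicative Gaussian noise to exact
Michaelis–Menten rates.

All generators are pure functions of their parameters and seed.

## Problem sizes used by tests and the acceptance script

Kinetic round trips use the 6-point substrate grid {2, 5, 10, 20, 50,
100} µM; Monte-Carlo bias/coverage uses 500 replicate fits at 5 % noise;
library composition uses 100 000 variants; the screen confusion matrix
uses 1000 variants at a 2 % active rate; NJ recovery uses 20 random
5–8-taxon trees. These sizes give stable statistics while keeping the
whole suite fast on a single core.

## Known limitations

- No indel model anywhere: alignment quality is assumed, not assessed.
- No among-site rate variation (Γ categories) and no branch-length or
  topology optimization by likelihood.
- The library composition model ignores fragment linkage (above).
- The screen model has no spatial plate effects; normalization is
  per-plate by design, so cross-plate comparability rests on the controls.
- HPLC rates assume equal substrate/product detector response unless a
  response factor is supplied.
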