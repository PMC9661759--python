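# Methods

This note records the models implemented in `cladescan`, their assumptions,
the defaults that matter, and the choices made where the design was open.

## Codon substitution models

All dN/dS machinery is built on the Goldman–Yang codon model over the 61
sense codons of the standard genetic code (plastid CDS translate identically
to the standard table over all sense codons; any NCBI table id can be
configured, which changes the state space accordingly). The instantaneous
rate from codon *i* to *j* is zero unless the codons differ at exactly one
nucleotide, and otherwise

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

with κ the transition/transversion ratio and ω = dN/dS. The chain is time-
reversible; transition matrices exp(Qt) are computed from the symmetric
eigendecomposition of D^{1/2} Q D^{-1/2} (D = diag π), which also lets many
ω classes be decomposed in one batched LAPACK call.

**Codon frequencies.** F3×4 (products of position-specific nucleotide
frequencies, stops removed, renormalized) is the default; F1×4, F61 and
uniform are available. Frequencies below 1e-8 are floored before
renormalization so that observed codons never carry zero likelihood.

**Site-class mixtures.** The supported ω-structures are M0, M1a, M2a, M3
(K = 3), M7 (beta, 10 equal-probability categories summarized by their
conditional means), M8, M8a (ωs ≡ 1), branch-site Model A and its null, and
Clade Model C with its null M2a_rel. Branch-heterogeneous classes assign
each tree edge to a partition: an edge belongs to a clade's partition iff
the leaf set it subtends is a subset of the clade, so the clade's stem edge
is included.

**Rate scaling.** Within one model, the unscaled generators of all classes
are normalized jointly by the mixture-averaged substitution rate (weights ×
per-class mean rate, evaluated on the background partition), so branch
lengths are expected substitutions per codon averaged over site classes.
The simulator applies the identical scaling, which is what makes simulated
parameters recoverable on the same scale. The standalone
`build_rate_matrix` scales its single matrix to mean rate 1.

**Likelihood.** Felsenstein pruning with per-node rescaling; gap/ambiguous
codons at a tip are missing data (partial likelihood 1 over all states),
never deleted columns. Identical site patterns are collapsed and expanded
after the per-class computation. The pruning implementation is checked
against exhaustive summation over all internal-node state assignments on
3–4-taxon trees, and against re-rooting invariance (time reversibility).

**Fitting.** `CodonModel.fit` maximizes the likelihood by bounded L-BFGS
over transformed parameters (log κ, log ω or logit ω for bounded classes,
stick-breaking logits for proportions, 1 + e^x for ω ≥ 1 classes), from a
deterministic start grid (M0 starts at ω ∈ {0.05, 0.5, 1.5, 3}), so refits
are bit-reproducible. Convergence tolerance is 1e-10 on the relative change
of −lnL. Branch lengths: the input tree is taken as estimated (it is an
input of the workflow, with its own branch lengths), and every model fits a
single multiplier of those lengths; non-M0 models warm-start κ and the
multiplier from a quick M0 fit. Full per-branch re-optimization is
available (`optimize_branches="full"`) but is not the default — the LRTs
compare models on the same tree, and per-branch noise adds cost without
changing the nested structure.

**Nested-fit guard.** Every null here is a boundary point of its
alternative's parameter space (zero weight or ω = 1 on the extra class).
The alternative is warm-started from the null's optimum; if optimizer
round-off still leaves it within 0.01 lnL *below* the null, the boundary
embedding is taken (lnL_alt := lnL_null). 2ΔlnL is clamped to zero only for
residual noise below 1e-6; larger violations raise.

## Likelihood-ratio tests

Site models: M0 vs M3 (df 4), M1a vs M2a (df 2), M7 vs M8 (df 2), M8a vs M8
(df 1). Branch-site: Model A vs Model A null, df 1. Clade model: CmC vs
M2a_rel, df = number of branch partitions − 1. p-values are upper-tail χ²
probabilities. For the boundary comparisons (M8a vs M8, Model A vs null)
the plain χ² reference is conservative relative to the 50:50 point-mass
mixture; plain χ² is used deliberately for simple p-value semantics, and
the calibration test verifies the resulting test is not anticonservative.
No multiple-testing correction gates any output; a Benjamini–Hochberg
q-value column is emitted for reference.

## Empirical Bayes site identification

NEB plugs the MLEs into Bayes' rule per site. BEB integrates over a uniform
grid prior on the mixture parameters with 10 points per dimension — class
proportions on the (i+0.5)/10 lattice (pairs restricted to the simplex),
ω0 on (0,1) bin midpoints, the positive-class ω on (1,11) bin midpoints —
with κ, codon frequencies, branch lengths and (for M8) the beta shape fixed
at their MLEs. BEB is provided for M2a, M8 and Model A; for CmC, where BEB
is not canonically defined, NEB is used. Sites are flagged `*`/`**`/`***`
at posterior probability 0.95/0.99/0.999 of the ω > 1 class.

## Clade-diagnostic (clade-private) mutations

A nucleotide column is private to a clade iff all clade members share one
non-gap, non-ambiguous state, that state occurs in no other taxon, and no
compared taxon is ambiguous at the column (strict diagnostic-character
behaviour; gap-vs-base differences are indels, never substitutions).
Privacy is a character-pattern property: a non-monophyletic clade triggers
a warning, not an error, and no ancestral polarity is inferred. Calls can
be restricted to a taxon subset (e.g. a single genus) to avoid reversions
contributed by distant outgroups. Events are annotated synonymous/
nonsynonymous at the codon level: nonsynonymous iff the carrier amino acid
is absent outside the clade.

Indels are called as maximal per-sequence gap runs; runs with identical
coordinates across sequences are one event carried by all of them, and an
event is in-frame iff its length is a multiple of 3. Gap-only columns are
retained by the reader precisely so that insertions relative to the other
taxa appear as such runs.

The ranking statistic for selecting candidate genes is clade-specific
nonsynonymous mutations per nt of CDS length; candidates are genes at or
above a configurable threshold (default 0.002), and an explicit override
list bypasses the threshold for exact reproduction of an external gene set.

## Amino-acid property Z-test

Replacements are located on the tree by Fitch parsimony on the translated
alignment; ambiguous assignments are resolved top-down, keeping the parent
state when possible and otherwise drawing uniformly under a fixed seed
(maximum-likelihood reconstruction is a configuration option). Tips with
gaps/ambiguity are unconstrained and emit no terminal-edge events.

Each replacement is graded per property into 8 equal-width bins spanning
the range of |Δproperty| over amino-acid pairs reachable by a single
nucleotide change, so category 8 is the most radical change a point
mutation can produce. The neutral expectation is the category distribution
of all single-nucleotide nonsynonymous codon changes, equally weighted
(codon-frequency weighting available). The one-tailed statistic for the
radical group (categories 6–8) is z = (obs − n·p̂)/√(n·p̂(1−p̂)), flagged at
2.33 (99%) and 3.09 (99.9%); only positive deviations are flagged. Windowed
scans use 15-codon windows, step 1, full windows only; windows without
events score z = 0.

Because the count statistic is binomial, the normal-approximation flag is
slightly anticonservative for properties whose radical probability is small
(exact attained level up to ≈0.014 at 1000 events, computed from the
binomial tail); the calibration test accounts for this discreteness
explicitly rather than altering the statistic.

**Property table.** The packaged table
(`data/aa_properties_synthetic.tsv`) is a synthetic reconstruction of the
standard 31-property set used in radical-change analysis: the property
names are the canonical list (alpha-helical tendencies … turn tendencies),
and the values are transcribed or approximated from the published
amino-acid-index literature (e.g. Kyte–Doolittle hydropathy, Grantham
polarity and molecular volume, Chou–Fasman secondary-structure tendencies,
exact molecular weights). It reproduces the one published calibration point
for the bin boundaries — Ser→Phe as the most radical possible change
(category 8) of mean r.m.s. fluctuation displacement — and is validated for
shape (31 × 20), symmetry and category extremes by the test suite. Users
with the original property set can supply their own TSV with the same
layout; all downstream statistics are table-agnostic.

## Per-site rate classes

A nucleotide GTR model (5 free exchangeabilities, empirical base
frequencies, one branch-length multiplier) is fitted by ML on the gene's
nucleotide columns. On top of the fixed GTR parameters a general discrete
rate distribution (default 4 classes, free rates and weights — the class
count is configurable; no gamma constraint) is fitted, and each column is
assigned its maximum-posterior class, ties breaking toward the slower
class. Degenerate (invariant) alignments are flagged and returned with
default parameters rather than failing.

## Synthetic data

`random_tree` draws a Yule topology with iid exponential branch lengths
(default mean 0.05 substitutions/codon — short branches typical of
within-genus plastome divergence). `simulate_alignment` draws each site's
class from the mixture, the root codon from the equilibrium frequencies,
and evolves along edges with the same scaled transition matrices the
likelihood uses; stop codons cannot be emitted, and the generating class of
every site is recorded for recovery tests. Diagnostic mutations are planted
by switching every clade member to a sense codon one nucleotide away from
the clade's current codon, with the derived state absent outside the clade
(re-drawing the site when impossible, with the realized site recorded);
indels are planted, not evolved. One RNG stream is keyed by the seed with
per-operation substreams derived by stable hashing of operation names, so
adding operations never perturbs existing fixtures.

What the generator deliberately does not emulate: among-site rate variation
beyond the ω mixture, indel evolution, base-composition heterogeneity
across lineages, alignment error, and recombination. Tests passing on this
substrate therefore validate the estimators and bookkeeping, not robustness
to real-data artefacts.

## Problem sizes and calibration defaults

Simulation-based checks run at sizes chosen to make their statistical
claims decidable while keeping the suite quick to iterate: M0 recovery at
8 taxa × 500 codons; M7-vs-M8 null calibration at 50 replicates of 6 taxa ×
200 codons (null beta(0.5, 2), mean ω = 0.2) with the power arm at 20
replicates (ωs = 3 on 10% of sites — power far exceeds the null rate, so 20
replicates order the two rates reliably); clade-private round trips on 100
fixtures of 5–10 taxa × 50 codons planted on invariant backgrounds so that
recovery must be exact; Z-flag calibration at 1000 events × 4000 replicates
per property, sampling the radical-count sufficient statistic directly.

## Known limitations

* The branch-site and M8a boundary LRTs use plain χ²; exact boundary
  mixtures would be slightly more powerful.
* BEB fixes κ, branch lengths and (for M8) the beta shape at their MLEs, as
  in the canonical grid construction; full joint integration is out of
  scope.
* The property table is a reconstruction (above); per-property values may
  differ from any specific historical distribution of the original tool,
  though the category semantics (equal-width bins over single-nucleotide-
  accessible ranges) do not depend on the exact values.
* Fitch parsimony underestimates replacements on long branches; the event
  counts feeding the Z-test are therefore conservative for deep
  divergences.
* The discrete-rate profile reports MAP classes; posterior uncertainty is
  available in `RateProfile.posteriors` but not summarized further.
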