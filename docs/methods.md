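# Methods

This note documents the statistical procedures, the synthetic-data
models, the numerical choices and the known limitations of `seedtox`.

## Screen normalization and ranking

Arrayed seed screens are run in *sets* (groups of plates sharing a
transfection batch), each containing wells of a non-targeting control
(siNT1 by default). Batch (set) effects are multiplicative on the
luminescence readout, so normalization divides each well by the mean raw
signal of its own set's control wells and multiplies by 100:

    viability% = 100 · raw / mean(raw of control wells in the same set).

Order of operations: wells are normalized to their set control first,
replicate wells of a seed within a cell line are then averaged, and cell
lines are averaged last (unweighted). Normalizing before any averaging
makes set effects cancel exactly — a property the acceptance suite
verifies on zero-noise simulations with arbitrary set effects. Sets
without control wells and non-positive control means raise typed errors.

Ranking sorts per-seed average viability ascending (rank 1 = most
toxic); ties are broken lexicographically by seed string so ranking is a
deterministic bijection. Toxicity classes use inclusive thresholds:
viability ≤ 10% ("reduces viability by 90% or more") is highly toxic,
≤ 50% moderately toxic. Missing (seed, cell line) cells propagate as NaN
and `rank_seeds` refuses to average over them unless `allow_partial=True`
is passed explicitly.

## Multinomial mixed model for logo comparison

### Model

Each seed is a cluster of six categorical observations (the nucleotide at
positions 1–6). For non-reference nucleotides k ∈ {A, C, U} (reference
G, configurable):

    log P(N_ij = k) / P(N_ij = G) = x_ij' β_k + (Z u_i)_k ,
    u_i ~ N(0, Σ_u),

with treatment-coded fixed effects (position 1 and the alphabetically
first group are baselines): intercept, group, position, group×position.
Random-effect structures:

* `unstructured` — u ∈ R³, one intercept per non-reference logit,
  Σ_u an unstructured 3×3 (log-Cholesky parameterized, 6 parameters);
* `diagonal` — independent per-logit intercepts (3 parameters);
* `scalar` — a single shared intercept loaded equally on all three
  logits (Z = 1₃, 1 parameter);
* `none` — no random effect: pooled multinomial logistic regression.

The per-seed intercept on the outcome logits induces within-seed
correlation across all six positions, which is the role the covariance
structure plays; it is a deliberate, testable reading of "cluster by seed
with unstructured covariance", and the scalar fallback is provided for
sensitivity analysis.

### Estimation

The marginal likelihood integrates the random effect per cluster. The
default is a Laplace approximation: the inner mode û_i maximizes the
penalized conditional log-likelihood (a strictly concave 3-D problem,
solved by vectorized Newton iterations across all clusters
simultaneously, warm-started between outer evaluations; inner tolerance
1e-10 on the gradient), and

    loglik_i ≈ ℓ_i(û) − ½ û'Σ⁻¹û − ½ log|Σ| − ½ log|H_i|,

with H_i the negative Hessian at the mode. For the 1-D scalar structure
an adaptive Gauss–Hermite rule (default 15 nodes, centered and scaled at
the mode) is available and agrees with Laplace to well under one
log-likelihood unit at desk scale. Outer optimization is L-BFGS-B over
(β, covariance parameters), started from the pooled multinomial MLE
(itself fitted by damped Newton–Raphson with analytic gradient and
Hessian); gradient tolerance 1e-6, max 500 iterations. Non-convergence
is flagged on the returned fit, never silent, and odds-ratio extraction
refuses non-converged fits.

### Inference

* Per-nucleotide group odds ratios: OR_k = exp(c'β_k) with the contrast
  c averaging the group difference over the six positions with equal
  weights (exact when no interaction is present, a marginal contrast
  otherwise). Wald standard errors come from the observed information of
  the fixed effects evaluated at the estimated covariance (finite-
  difference Hessian; the covariance parameters are held fixed, the
  usual mixed-model Wald convention).
* Omnibus group and group×position tests: likelihood ratio between
  nested fits, χ² with df = difference in fixed-parameter count.
* Degenerate group×position cells (a nucleotide never observed) emit a
  `SeparationWarning`; no pseudo-counts are added — the random effect's
  partial pooling is relied on, and estimates near separation should be
  read with care.

Validated limits: with structure `none` the coefficients equal an
independent multinomial-logit implementation to ~1e-15; parameter
recovery at the simulated study scale (2×100 seeds, planted OR_A = 2.5,
diagonal Σ = 0.25·I) gives a median OR_A ≈ 2.5 over 20 replicates with
95% Wald-CI coverage ≈ 95%; relabeling the reference nucleotide
transforms pooled-fit odds ratios consistently
(OR_{A|G} = OR_{A|C}·OR_{C|G}).

## Seed matching

The seed is guide positions 2–7 (1-based, 5′→3′) after stripping vendor
chemistry markup (r/m prefixes; DNA overhang letters are transcribed and
retained — they fall outside the seed). The seed match is the reverse
complement in the RNA alphabet, written 5′→3′. Word counting is
case-insensitive, T≡U, and counts *overlapping* occurrences with 0-based
start positions, so the counts of all 4096 words in a sequence of length
L sum to L − 5 (window conservation, required for the landscape test's
totals). Isoform resolution keeps the longest sequence per gene
(FASTA ids are collapsed at the first `|`).

## Enrichment

**Hypergeometric landscape.** Genes are ranked from most down- to most
up-regulated (stable sort by (statistic, gene id)). At each cutoff t
(default grid: every 100 genes plus the full list), for each word w, the
leading t genes' windows are a draw of n from the N total 6-mer windows,
with K total occurrences of w; observing x occurrences in the leading
set gives the upper-tail p (over-representation, plotted as −log10 p,
positive) or lower-tail p (depletion, negative), choosing the tail by
comparing x with its expectation nK/N. The significance line is
Bonferroni-corrected for the 4096 words tested: −log10(0.05/4096) ≈ 4.91.
The dialect is occurrence-based with no Markov background correction and
no sequence trimming. Note the line corrects across words, not across
cutoffs: under a true null the *global* maximum over all words and
cutoffs still exceeds the line occasionally, while any *named* word's
landscape rarely does — per-word statements are the intended use.

**eCDF shift test.** One-sided two-sample Kolmogorov–Smirnov with
alternative "greater" oriented so that it tests whether seed-match-
containing genes are shifted toward lower logFC: D = sup_x [F_with(x) −
F_without(x)]. Exact p-values when n·m ≤ 10⁴ (verified during
development against exhaustive labeling enumeration), asymptotic
otherwise.

**Pre-ranked enrichment score.** Running sum over the ranked list: every
position decrements 1/N, a hit adds its normalized weight
|statistic|^p / Σ_hits |statistic|^p (default p = 1; p = 0 gives the
classical K-S statistic of the hit ranks against uniform, with the
closed-form boundary value 1 − m/N when the set is the first m genes).
ES is the extreme deviation of this bridge, in [−1, 1]. The permutation
p-value draws random gene sets of the same size (default 1000 draws,
seeded, +1-corrected), counting permutation scores at least as extreme
in the observed direction.

## Target selection

The nomination chain keeps rows with baseMean ≥ 1000 (inclusive),
adjP < 0.05 (strict), log2FC < −1 (strict; symmetric for up/both), and
seed-match count ≥ 1, sorted by log2FC ascending; the count surviving
each step is recorded in provenance. Top/bottom-n slices must be
disjoint (table ≥ 2n). Match-count comparison uses the equal-variance
two-sample t (Welch by flag); two identical zero-variance groups return
p = 1 by convention. Control genes are the n smallest-|log2FC| genes
among those with baseMean > 1000 and zero seed matches.

## Synthetic-data models

All generators are pure functions of their parameters and `rng_seed`
(byte-stable outputs), and every planted truth is recomputable by the
analysis modules.

**Screen.** Expected viability maps a position-weighted G score
g(seed) = Σ_p w_p·1[seed_p = G] through a decreasing logistic onto
[5%, 110%]. Default weights (1.0, 0.9, 0.75, 0.55, 0.35, 0.2) decay
5′→3′ so G at the 5′ end is most toxic — the qualitative structure of
real screens; midpoint 1.8 and scale 0.55 put all-G seeds near 6% and
G-free seeds above 100%. Wells get multiplicative log-normal set effects
(sd 0.25 on the log), additive Gaussian viability noise per cell line
(default 4 percentage points, truncated at 0), triplicate wells, three
sets per cell line, nine siNT1 control wells per set. What this does not
emulate: plate-position (edge) effects, signal drift, or cross-cell-line
toxicity differences — passing tests show the normalization algebra and
rank logic are right, not that real plate artifacts are handled.

**Transcriptome.** UTR lengths are log-normal (median 500 nt, clipped to
[60, 3000]); a gene has no seed match with probability 0.6, else
1 + Poisson(1) matches, planted non-overlapping on a 6-nt grid into a
uniform-random background that is scrubbed of accidental occurrences
(the generator verifies the final count equals the planted count
exactly and raises otherwise). log2FC = −β·(match count) + N(0, σ) with
defaults β = 1, σ = 0.5 — chosen so detection tests have comfortable
power at 1000 genes; baseMean is log-normal (median 800, sdlog 1.2);
adjP is a Benjamini–Hochberg-adjusted two-sided z-test of log2FC/σ.
Real 3′ UTRs are not uniform-random (composition bias, repeats,
length–expression correlation), so these tests demonstrate algorithmic
correctness and planted-signal power, not performance on genomic
sequence.

**Logo groups.** Per-seed random effects u ~ N(0, Σ_true) are added to
baseline logits of (A, C, U) vs G plus a per-group log-OR shift; each
position draws one nucleotide from the implied multinomial. Defaults
(100 seeds/group, shift log 2.5 on A for the second group, Σ_true =
0.25·I) define the recovery-test conditions.

## Numerical choices and degenerate inputs

* Inner Newton tolerance 1e-10, outer L-BFGS-B gtol 1e-6/ftol 1e-11; a
  1e-10 ridge on Σ during line searches guards near-singular proposals.
* Hypergeometric tails come from scipy's exact implementation; signed 0
  is returned for empty or whole-population leading sets.
* All ties (seed ranking, ranked gene lists, control-gene selection) are
  broken by identifier so every ordering is reproducible.
* Constant vectors are rejected by `screen_correlation`; empty groups by
  `ecdf_ks`; gene sets equal to or disjoint from the ranked list by
  `preranked_es`; negative viabilities by the toxicity classifier.

## Scale of the shipped simulations

The test and acceptance simulations use 2×100-seed logo replicates,
512–4096-seed screens and 1000-gene transcriptomes — sizes chosen to
give each stochastic check ≥80% empirical power while keeping a full run
in minutes on a laptop. Larger runs only sharpen the same estimates.

## Known limitations

* The mixed model's covariance is on the outcome logits, not a 6×6
  across-position matrix; a position-indexed random effect would need
  18-dimensional integrals per cluster and is out of scope.
* Wald CIs condition on the estimated random-effect covariance and can
  be slightly anticonservative near the boundary Σ → 0.
* The landscape implements a single occurrence-based hypergeometric
  dialect; Markov background correction used by some published k-mer
  tools is not implemented.
* Differential expression estimation itself is out of scope: DE tables
  are inputs, and the synthetic adjP model is a convenience, not an
  RNA-seq error model.
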