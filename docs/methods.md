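# Methods

## The prediction problem

A primer–template pair (PTP) either produces a visible amplicon under
standard *Taq* PCR or it does not. `primeramp` models the probability of
amplification from two pair-level quantities: the free energy of annealing
ΔG of the most likely binding conformation, and the position i_X of the
3′-hexamer mismatch closest to the primer's 3′ terminus. Both capture
established PCR biology — annealing stability drives heteroduplex
formation, and 3′-terminal mismatches disrupt polymerase extension with
severity increasing toward the terminus — without requiring base-identity
specific mismatch effects, which are deliberately out of scope (they are
poorly identifiable from gel-electrophoresis endpoints, and all primers in
the reference data terminate in G/C).

## Binding-mode search

The primer is slid ungapped across the template (sense-strand convention:
a forward primer is compared base-for-base against the strand it copies).
Every fully contained offset is scored; the conformation minimizing the
number of mismatches is the binding mode. Design choices:

* **IUPAC degeneracy counts as a match** when the two codes' expansions
  intersect: a degenerate primer position is synthesized as a base
  mixture, so at least one molecule pairs perfectly. N matches everything.
* **No overhangs, no gaps.** Templates are assumed to contain the complete
  annealing region (full leader upstream of the target gene), so partial
  overlaps are rejected, and indel conformations are not modeled.
* **Ties** between equal-mismatch offsets are broken by annealing ΔG when
  a thermodynamic scorer is supplied (as `featurize_pair` does), otherwise
  by smallest offset — determinism is required for testability.
* Reverse-complement search exists behind an explicit flag, off by
  default.
* Hexamer positions are reported 1-based with j = 6 at the 3′ terminus;
  internal coordinates are 0-based half-open.

Pairs whose best conformation still has more than 12 mismatches are
excluded from modeling (`filter_by_mismatches`): at that divergence the
annealing site itself is uncertain.

## Nearest-neighbor thermodynamics

ΔG = ΔH − T·ΔS/1000 is summed over dinucleotide steps plus per-end duplex
initiation terms, at the set-specific annealing temperature (55 °C
default; 57 °C for the second primer-set style). Parameters are the
unified Watson–Crick set plus the published internal single-mismatch
series, taken from Biopython's `MeltingTemp` tables (`DNA_NN3`,
`DNA_IMM1`; 1 M Na⁺ reference) and validated complete on load — all 16 WC
and 96 single-internal-mismatch steps resolve. The parameter set is
pluggable: any plain-text `step ΔH ΔS` table with a source header can be
loaded, and the source label is stamped into every result.

Numerical/coverage choices:

* **Tandem (adjacent) and duplex-end mismatches** are not covered by
  published single-mismatch tables; such steps contribute a configurable
  neutral term (default 0 kcal/mol) and are flagged in
  `AnnealingResult.fallback_steps`. A mismatched terminal pair also
  forfeits its initiation term.
* **Degenerate bases** are resolved, for energetics only, to the
  expansion matching the partner base when possible, else the first
  expansion alphabetically.
* **No salt or concentration correction** is applied by default.
* Self-dimerization ΔG is the minimum over all ungapped overlaps (length
  ≥ 2) of the primer against its own reverse complement, clamped at 0.
* Exact parity with any particular hybridization program is **not** a
  contract of this module; modeling operations can equally consume an
  externally computed feature matrix (`read_feature_matrix` with a
  `column_map` for foreign headers), so model results do not depend on
  thermodynamic parity. Unimolecular folding energies and melting
  temperatures are out of scope.

## Feature encodings

For the chosen conformation, z ∈ {0,1}⁶ marks mismatches within the 3′
hexamer (z_j = 1 iff position j mismatches, j = 6 terminal), X_N = Σ_j z_j
counts them, and i_X = max{j : z_j = 1} (0 if none) locates the one closest
to the terminus. These identities are enforced as invariants on every
`FeatureVector`. Primer-intrinsic descriptors are computed alongside:
GC ratio counts G, C and the S code only (other degenerate codes are
excluded from the numerator — note that fractional ambiguity counting
would be an alternative convention); GC-clamp extent is the G/C run ending
at the 3′ terminus, uncapped; the longest homopolymer run is descriptive
only. Primers shorter than 6 nt are rejected rather than zero-padded.

## Labels and splits

Each pair is measured in triplicate and read by five reviewers: a
reviewer calls the pair Amplified iff ≥ 2 of 3 lanes show a band; the
consensus label is Amplified iff a strict majority of reviewers agree
(ties fall to Unamplified). Retained pairs are split 25% validation / 50%
training / 25% testing: validation and testing sizes are floored at their
fractions and the remainder trains, which reproduces 227/454/227 at
N = 908. Splits are seeded and serialized as JSON manifests. Because the
original split seed is unknowable, split-dependent quantities are treated
as stochastic and reported across seeds rather than claimed exactly.

## Model fitting and selection

Logistic regressions are fitted by IRLS (statsmodels GLM, binomial
family; tolerance 1e-8, ≤ 100 iterations), with Amplified coded 1.
Perfectly collinear design columns are detected by rank-revealing QR
(tolerance 1e-10, later column of a dependency loses) and flagged
*aliased* with NaN coefficients — exactly what happens to X_N when all of
z1..z6 are present. Single-class data and perfect separation raise a
diagnostic error instead of silently diverging. Wald per-coefficient
p-values are reported; no regularization is applied (the term count is
small). AIC = 2k − 2 ln L̂ counts only estimated coefficients.

Backward stepwise selection greedily removes the single term whose
removal most lowers the AIC, subject to marginality (a main effect is
protected while its interaction remains), and stops when every removal
would raise the AIC. One refinement: a removal that leaves the AIC
*exactly* unchanged is accepted (parsimony at a tie). This matters
precisely in the redundant-design case above — with all of z1..z6 and
X_N = Σ z_j present, dropping any one redundant column leaves the fitted
subspace, hence the AIC, bit-identical, and a strictly-decreasing rule
would stall on a model containing provably superfluous terms. Ties are
otherwise measure-zero. Note that AIC-guided selection is not
selection-consistent: a pure-noise term survives whenever its deviance
improvement exceeds 2 (≈ 16% each), so simulation tests of "nuisance terms
pruned" fix their generator seed.

The published TMM coefficients (−5.6177, −1.5448, 0.3279, 0.1837 for
intercept, ΔG, i_X, ΔG·i_X) ship as package data with their Wald
p-values, provenance, and probability-scale classification cutoffs
(0.839 high-specificity, 0.461 Youden). The free-energy baseline FE
scores a pair by ΔG itself and classifies Amplified iff ΔG < cutoff
(strict).

## Evaluation

The AUC is the Mann–Whitney probability that a random Amplified score
outranks a random Unamplified one (ties half). Cutoff search evaluates
every midpoint between adjacent distinct scores plus sentinels half a
mean gap beyond the extremes, so all achievable classifications are
reachable with the strict-inequality decision rules; a selected cutoff
may therefore sit just beyond the extreme observed score when the optimum
is a degenerate all-one-class rule. Youden's cutoff maximizes
sensitivity + specificity − 1, ties broken toward higher specificity (the
conservative direction for multiplex design, where a false positive can
silently cost template coverage); the high-specificity cutoff maximizes
sensitivity subject to empiric specificity ≥ 0.99, which the
all-Unamplified sentinel always satisfies. Undefined metric ratios are
reported as `None`, never 0.

Probability-model cutoffs are selected by 10 runs of 5-fold
cross-validation on the validation set: per run, held-out scores are
pooled and both cutoffs computed; the final cutoff is the across-run mean
(the aggregation choice is recorded in the output trace). Folds whose
training part is single-class are redrawn under a fresh seed, logged.
Score-only models (FE) take their cutoffs directly on combined
training + validation data, a distinct non-CV path. Rank comparisons
between groups use the two-sided Mann–Whitney test, exact for tie-free
samples of ≤ 50 per group and normal-approximated with tie correction
otherwise.

## Synthetic data

`synthesize_dataset` draws labeled pairs under the model's own law:
ΔG ~ Uniform(−20, −1) kcal/mol (spanning the inter-quartile ranges
observed in real primer-coverage data, and bounded within [−25, 0]); i_X
categorical over 0..6 with P(0) = 0.30 and mass increasing toward the
terminus (0.06, 0.08, 0.10, 0.12, 0.16, 0.18), matching the observed
concentration of hexamer mismatches at j = 5–6; a mismatch planted at
position i_X with independent extras at lower positions (rate 0.3);
out-of-hexamer mismatches ~ Poisson(2); label ~ Bernoulli with
logit p = β₀ + β₁ΔG + β₂i_X + β₃ΔG·i_X at the published coefficients by
default. A point ΔG range (lo = hi) is allowed for closed-form checks;
inverted or out-of-bounds ranges are rejected. Everything is reproducible
under a single seed.

What the generator does **not** emulate: the strong empirical association
between ΔG and i_X (real mismatches destabilize the duplex; here the two
are drawn independently, which is deliberately well-conditioned for
parameter-recovery tests), primer-set structure, base-identity effects,
and template secondary structure. Passing simulation tests therefore
demonstrate correctness of the estimation and evaluation machinery under
the model's own law — not transferability of the published coefficients
to new chemistry.

## Problem sizes used in the test suite

Parameter recovery uses n = 20,000 draws (coefficients recovered within 3
standard errors); law-of-large-numbers label checks use n = 50,000
(tolerance 0.01); stepwise pruning uses n = 6,000; oracle-equivalence
suites use ≥ 100 random binding instances and ≤ 200-point score sets.
These sizes give comfortable statistical margins while keeping the full
suite around ten seconds on one core.

## Known limitations

* The TMM is calibrated on gel-electrophoresis endpoints for IGHV
  amplification with G/C-terminated primers of favorable intrinsic
  properties; it omits primer- and template-specific factors and likely
  overestimates amplification for primers with poor self-structure or
  templates with stable secondary structure.
* The thermodynamic module's tandem/terminal-mismatch fallback is
  conservative and flagged, not parameterized.
* DECIPHER's elongation-efficiency comparator (DE) is not reimplemented;
  its printed cutoffs (9.71e-05 and 1.88e-05) are documented for users
  who wish to adapt it externally.
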