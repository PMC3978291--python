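# Methods

This note documents the models and estimators implemented in `symcomplex`,
the conventions chosen where several were defensible, the synthetic study
conditions, and the limitations a user should know before interpreting
numbers.

## Symbolization

A trajectory sampled as `(t_ms, x_cm, y_cm)` is coarse-grained by a grid of
square cells (default 10×10 cells of 1 cm in a 10×10 cm workspace). Cells
are half-open, `[i·s, (i+1)·s) × [j·s, (j+1)·s)` from a lower-left origin;
`x` increasing emits `r`, `y` increasing emits `u`. One symbol is emitted
per boundary crossing; a sample pair that crosses several boundaries emits
them in the order of the linear-interpolation crossing parameter along the
segment, with exact corner ties broken by the larger absolute displacement
component, then x-first. Crossing-time ordering was chosen over pure
displacement ordering because it is the unique convention consistent with
densely resampling the segment and recording crossings one at a time; at
1 kHz sampling, multi-boundary intervals are vanishingly rare anyway.
Samples outside the workspace are clamped within 1e-6 cm (physical walls
make larger excursions an input error). Per-trial sequences are merged
with no separator; junction indices are retained so consumers can
optionally reset model context at boundaries (off by default, matching
online learning across an entire session).

Any consistent relabeling of the four symbols leaves the entropy-based
measures exactly invariant (tested); the CTW measures are only
approximately invariant because the 8-bit ASCII codes are not
permutation-equivariant — observed differences are far below
cross-condition effects.

## Context-Tree Weighting

Each symbol is expanded into the 8 bits of its ASCII code and eight binary
context trees run in parallel, tree *i* conditioning on the depth-D history
of *its own* bit stream (D = 8 bits = 8 past transitions; contexts are
zero-padded at the start). Nodes hold Krichevsky–Trofimov counts; the
weighted probability follows the ½/½ leaf-versus-split recursion, computed
entirely in the log domain with log-sum-exp so that length-10,000 sequences
(total probabilities near 2^-20000) remain exact. Per-bit predictive
probabilities are the ratio of the root weighted probability with and
without the candidate bit; they sum to 1 to machine precision, and the
depth-1 recursion was verified against an explicitly enumerated two-model
Bayes mixture on all 256 length-8 strings.

Prediction: a candidate symbol's probability is the product of its eight
per-bit probabilities renormalized over the four valid symbols;
the maximum-probability symbol is predicted, ties broken in the fixed
alphabet order `l < r < u < d` (relevant only for fully symmetric states
such as the untrained model). Predictability γ counts exact one-step-ahead
hits over the whole sequence, predicting before updating.

Compression: the byte-stream probability doubles as an ideal
arithmetic-coding distribution; `N_comp = ceil(−log₂ P) + 2` bits, the
standard arithmetic-coding guarantee, instead of a bit-exact coder — only
differences between conditions are interpreted. Note that independent
per-bit trees cannot exploit cross-bit redundancy: an i.i.d. uniform
4-symbol source costs ≈ 4.2 bits/symbol rather than the 2 bits/symbol a
joint coder would approach, so η_CTW ≈ 0.47 (not 0.75) for such input.
This offsets every condition equally and leaves orderings intact.

## Approximate entropy

The classic six-step procedure: length-m embedding vectors, Chebyshev
distance, strict `d < r` match counts including the self-match, φ as the
mean natural log of match fractions, ApEn = φ^m − φ^{m+1}. Symbols are
coded l→1, r→2, u→3, d→4 and r = r_factor·σ (population SD). Because
σ ≤ 1.5 for four integer levels and r_factor ≤ 0.25, r < 1 always holds on
symbol input and matching reduces to exact template equality — which is why
ApEn is r-independent here; an O(N) counting path exploits this and is
verified against the direct O(N²) pairwise implementation. σ = 0 (constant
input) returns 0 with a warning: a constant sequence is maximally regular.
ApEn of the strict alternation is ≈ −1e-8 rather than exactly 0 — the
m+1-block count asymmetry of a finite even-length alternation — and is
reported as computed.

## Lempel-Ziv

`lz76_parse` implements exhaustive-history parsing: each phrase is the
shortest prefix of the remainder not reproducible by copying (with
self-overlap) from the preceding text; the final fragment counts as one
phrase. The entropy-rate estimator is the normalized complexity
ĥ = c(N)·log_k(N)/N, clipped to [0, 1]. Among the textbook normalizations
this one is accurate for memoryless and Markov sources (+0.4% at N = 10⁵ on
a persistent chain, −1.4% for i.i.d. uniform); its known slow
O(log log N / log N) convergence shows on the boundary-constrained 10×10
walk, where it reads ≈ +5% high at N = 10⁵ (the alternative
c·(log_k c + 1)/N form converges for the walk but underestimates the other
sources by ~8%, which would be worse for every downstream use). The
dictionary compressor is LZW with the four single symbols preloaded and
growing code width (⌈log₂ table size⌉ bits per token); a paired decoder
verifies losslessness.

## Entropies and effective measure complexity

Block entropies H_L are plug-in estimates over overlapping windows in
base-4 units; conditional entropies h_L = H_{L+1} − H_L with h_0 ≡ H_1, so
the L = 0 term of the EMC sum contributes H_1 − h and the total coincides
with the standard excess-entropy definition. Negative empirical gains
(possible by noise) are clamped to zero. Empirical orders are limited by
L_max + 1 < log₄ N — L_max = 4 for N = 10,000 — and the call refuses less
reliable orders unless forced. The tail is the polynomial decay
h_L ≈ h + L^(−α), fitted by no-intercept least squares of log(h_L − h) on
−log L over the reliable orders with excess > 1e-6; with fewer than two
usable orders (or a non-decaying fit) the profile is degenerate and only
empirical excesses are summed. Because α < 1 makes the infinite sum
diverge, the interpolated sum is truncated at L_trunc = 64 (configurable,
reported with the estimate). EMC estimates inherit the rate estimator's
bias: a memoryless source reads ≈ 5 × (rate bias) ≈ 0.07 rather than 0 at
N = 10⁵; cross-condition contrasts, which are the intended use, are two
orders of magnitude larger.

`entropy_rate_random_walk` gives the exact rate of the uniform
boundary-constrained walk: the stationary distribution of a random walk on
the grid graph weights each cell by its number of admissible moves, so
h = Σ_c π(c)·log₄ moves(c); 0.93355 base-4 units for 10×10. It serves as
the independent oracle for the LZ estimator and the walk generator.

## Synthetic study conditions

No movement recordings ship with the package; the synthetic module defines
the study conditions, 10,000 transitions each (50 trials × 200), one seed
per simulated subject:

- **AS** strict alternation `udud…`.
- **AR** uniform random walk on the 10×10 grid, started at the center.
- **AF** i.i.d. symbols with the first-order frequencies of the same
  seed's pattern sequence, unconstrained by the grid (a grid-constrained
  variant could not match the target frequencies exactly).
- **P** (pattern-like): one closed loop motif (rectangles and staircase
  diamonds, perimeter 8–20), repeated from a start cell where its bounding
  box fits; with probability 0.005 per symbol an admissible random move is
  substituted and immediately undone, and with probability 0.02 per
  completed cycle the motif is replaced — emulating a subject repeating a
  chosen pattern with occasional slips and occasional pattern changes.
- **L** (letter-like): uniform random concatenation of a fixed library of
  12 stroke motifs of length 8–16 (non-reversing walks) — fixed letter
  shapes drawn in random order.
- **R1** (random-like): uniform random concatenation of a large repertoire
  of 32 short fragments (length 6–9) — self-paced "random" drawing
  modeled as an unpredictable stream of habitual motor primitives. A
  first-order Markov walk is too shallow for this role: its excess entropy
  is bounded by H₁ − h, which no chain irregular enough to sit between
  letters and the uniform walk can push above the alternation's 0.5;
  fragment concatenation carries structure across several orders, as human
  random motion does. (Order-1 chains with analytic rates, and a two-mode
  sweep/jitter walk, remain available as validation sources.)

Surrogate parameters were calibrated once so that the surrogates span the
region between the artificial extremes on all measures, then frozen. With
these defaults the suite reproduces, over 10 seeded subjects with rank
tests: the irregularity ordering AS < P < L < R1 < AR on predictability,
LZ compressibility, ApEn (m = 1 and 2), and LZ complexity; and the
complexity ordering EMC(P) > EMC(L) > EMC(R1) with all three artificial
processes below every surrogate. What passing this does **not** show:
the surrogates lack curvature statistics, speed modulation, boundary
avoidance, and inter-subject variability of real drawing; absolute
surrogate values are not comparable to human data, only the relational
structure is.

The continuous generators (circle, Lissajous, reflected Brownian, and an
Ornstein–Uhlenbeck-velocity "smooth scribble") exist to exercise the
symbolization layer and the grid-size sweep. In the sweep, the scribble
shows the expected monotone rise of predictability with finer grids
(longer uniform runs per stroke) while unnormalized LZ complexity grows;
noiseless closed curves instead sit near the predictability ceiling where
two artifacts dominate — coarse grids leave only a handful of admissible
transitions, and very fine grids create runs longer than the CTW context
depth whose endpoints are unpredictable — so the monotonicity claim is
asserted for the stochastic trajectory only.

## Pursuit game

A persistent CTW model (depth 8) predicts each grid move of an evader
policy before seeing it; per-trial hit fractions are recorded, 200
transitions per trial, learning carried across trials. Evader policies are
package constructs standing in for players: `uniform` (admissible moves
uniformly; caught at chance ≈ 0.25), `anti_map` (moves to the predictor's
least probable admissible symbol; an upper bound on evasion),
`softmax_evasive` (feedback-modulated softmax away from the predictor).
Online feedback exposes per-move hits to the policy, offline only the
end-of-trial fraction; with a feedback-blind evader the two modes are
statistically indistinguishable by construction, which the tests confirm.

## Statistics

Condition contrasts use the two-sided Mann–Whitney–Wilcoxon test with
Bonferroni–Holm step-down correction; the correction family is the set of
pairwise contrasts within one measure. Stars: * p<0.05, ** p<0.01,
*** p<0.001 on adjusted p-values. All-tied groups report p = 1 with a
warning.

## Reproducibility and problem sizes

Every generator is a pure function of (parameters, seed); pipeline runs
write a provenance block (config hash, seed, version). Default analysis
sizes — sequences of 10⁴, entropy-rate checks at 10⁵, 10 subjects per
condition, 25–50 pursuit trials — keep a full validation run in a few
minutes on one core while leaving every reported contrast far from its
significance threshold.
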