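# Methods

## The problem

People execute the same movement in recognizably different ways, and the
same person varies from trial to trial. `motordist` operationalizes the
notion of *motor distance* — a scalar dissimilarity between two individuals'
movement repertoires — for upper-limb reach-to-grasp movements recorded by
motion capture. The method's validity hinges on a ground truth: within
reasonable trial-to-trial variability, a person moves more like themselves
than like other people. The pipeline is therefore designed around a dataset
layout in which one person (the "confederate") contributes many sessions,
each treated as a separate subject-instance, so within-person distances are
observable alongside between-person ones.

## Trial representation

Each pre-windowed trial (reach onset to offset) becomes a 10 × 3 matrix:
10 time points × (WV, WA, WJ).

* **WV** (wrist velocity, mm/s) — the module of the first derivative of the
  wrist marker position.
* **WA** (wrist acceleration, mm/s²) — the rate of change of WV. WA defined
  as the module of the acceleration vector is also implemented
  (`wa_definition="acceleration_module"`); the two readings coincide for
  straight paths and differ on curved ones. The signed d(WV)/dt reading is
  the default because it preserves the deceleration phase as negative
  values.
* **WJ** (wrist jerk, mm/s³) — the rate of change of the module of the
  acceleration vector.

Positions are low-pass filtered per axis before differentiation — once, on
the trajectory, rather than on each derived variable, because
differentiation amplifies any residual noise. The filter is a 2nd-order
Butterworth at 8 Hz (100 Hz sampling), applied forward and backward
(`filtfilt`): zero phase lag, effective 4th-order magnitude response.
Derivatives are central differences on interior samples and one-sided at
the endpoints, with dt = 1/sample_rate.

Time normalization divides the movement into 10 non-overlapping deciles and
averages each variable within bins; bin *b* (1-based) covers 0-based sample
indices [⌊(b−1)N/10⌋, ⌊bN/10⌋), a floor-based rule that is deterministic and
exhaustive for any N ≥ 10. In shape-analysis terms the 10 time points are
landmarks in the 3-D (WV, WA, WJ) space. The three variables are kept in
their physical units: no per-column standardization is applied, so the
column with the largest dynamic range (WJ) dominates the centered sum of
squares. This is a property of the representation, not an artifact of this
implementation.

## Procrustes distance

Two trial matrices are compared by ordinary Procrustes superimposition with
translation, rotation, optional reflection and isotropic scaling, via the
classical SVD solution: center both matrices, normalize each to unit
centered Frobenius norm, decompose the cross-product X₀ᵀY₀ = U S Vᵀ, take
T = V Uᵀ, and read the normalized distance off the singular values:

    d = 1 − (Σᵢ σᵢ)²  ∈ [0, 1].

This is the residual sum of squared point differences standardized by the
target's centered sum of squares; the standardization is what confines d to
[0, 1] and makes it symmetric in its arguments (asserted to 1e-12 at run
time). Rotation is always part of the fitted group: the named reference
semantics for this operation include it, and the pure
translation/scale/reflection subgroup is not a useful shape match.
Degenerate matrices (all landmarks identical) are rejected with an explicit
error rather than assigned a sentinel distance — they cannot arise from real
movement and indicate an upstream problem.

With reflection disabled the determinant of T is forced to +1 by flipping
the axis of the smallest singular value, which yields the best proper
rotation; the resulting distance can only be larger.

## Inter-trial alignment (FPT trial)

A subject's t retained trials are collapsed into one representative: one
trial is the target (default: the first available; an index or trial id can
be supplied instead, and `target_sensitivity` quantifies how little the
final distance structure depends on the choice), every other trial is
Procrustes-fitted onto it, and the 10 × 3 × t stack — the target enters
untransformed, so the stack size equals the retained-trial count — is
averaged across t into the final Procrustes-transformed (FPT) trial.
Element-wise standard deviation over the stack records inter-trial
variability; the population convention (divide by t) is the default since
the SD describes this fixed stack, with `sd_ddof=1` available. The scheme
is deliberately one-pass: trials are not re-fitted to the evolving mean
(no generalized-Procrustes iteration).

## Distance matrix and inspection

FPT means are compared pairwise, producing a labelled symmetric n × n
matrix with zero diagonal and off-diagonal entries in [0, 1]. Both fit
directions are computed and averaged, so symmetry holds bit-exactly rather
than to rounding. For the study design (16 + 16) this gives 496 unique
couplings: 120 within each group and 256 across. The participant–participant
and confederate–confederate blocks are both treated as 120-cell
upper-triangle blocks of the symmetric matrix; the 256-cell enumeration
applies to the cross block.

`rank_neighbours` sorts a reference subject's column and flags the nearest,
33rd-percentile, 66th-percentile and farthest comparators (1-based rank
⌈q·(n−1)⌉, ties broken by label), supporting the qualitative inspection of
kinematic profiles of similar vs dissimilar subjects.

## Statistical machinery

**Swap test.** Observed statistic: mean of the confederate–confederate
upper-triangle block. Each of the 1000 (default) permutations replaces a
uniformly drawn block cell (i, j) with the distance between confederate i
(the first member of the couple is retained) and a uniformly drawn
participant, and recomputes the mean. p is the fraction of permutations
that *strictly* reduce the mean; ties do not count, which is the
conservative reading of "reduce". Draws are independent across iterations.

**MDS.** Initialization by classical scaling (double-centered squared
distances, top-2 eigenvectors scaled by root eigenvalues), refined by
iterative stress majorization (Guttman transform), tolerance 1e-6 on the
relative stress decrease, at most 300 steps. Goodness-of-fit is Kruskal
stress-1 over the upper triangle; the majorization guarantees a
non-increasing stress sequence, which is recorded and asserted in tests.

**ICC robustness.** For removal fractions 10%–80% in steps of 10%, each
subject keeps max(2, round((1−f)·t)) trials drawn uniformly without
replacement; alignment and the distance matrix are recomputed per
iteration, the iteration matrices averaged, and agreement with the
full-data matrix quantified as ICC(A,1) — the two-way, single-measurement,
absolute-agreement intraclass correlation,
(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)) with k = 2 — on the
paired upper-triangle vectors. Absolute agreement (not consistency) is the
point: a reduced matrix that is merely proportional to the full one is
penalized.

**Mantel test.** Pearson correlation between the two matrices' upper
triangles; 5000 (default) joint row-and-column relabellings of the second
matrix; one-sided p for positive association. By default the observed
statistic is included in numerator and denominator (p ≥ 1/(n_perm+1)); a
pure-count convention, which can report p = 0, is available.

**IMS baseline.** The individual-motor-signature method compares one
variable at a time: per-variable RMSE matrices over the 10 FPT time points,
each divided by its maximum off-diagonal entry (mapping to [0, 1] — of the
plausible normalizations, max-scaling is the one that makes the averaged
matrix share the Procrustes matrix's range; z-scoring or unit-sum would
not), then averaged. IMS is computed on the same FPT representations as the
Procrustes path, so the comparison isolates the distance computation
itself rather than differences in preprocessing. `method_comparison`
substitutes, one cell at a time (exhaustively, not by sampling), the IMS
value into the Procrustes matrix and counts the fraction of substitutions
that strictly reduce the block mean.

## Synthetic data generator

The generator exists so the whole pipeline can be validated against a known
ground truth without motion-capture data. A subject's style is
(D, T, γ, C): reach amplitude 200–400 mm, movement time 0.6–1.4 s,
asymmetry exponent 0.75–1.3, path curvature 5–40 mm, drawn uniformly from
those ranges. The trajectory is the minimum-jerk path
x(τ) = D(10u³ − 15u⁴ + 6u⁵) with u = τ^γ — the standard point-to-point
reach model, chosen because it is closed-form checkable (peak speed
15D/(8T) for γ = 1) and produces realistic bell-shaped WV with plausible WA
and WJ — plus a curvature bow C·4s(1−s) in a second axis. Trial noise has
two independent dials, mirroring the premise that within-subject
variability is real but smaller than between-subject variability:
multiplicative Gaussian jitter (CV 0.05) on D, T and γ per trial, and
smooth additive positional noise (white noise Gaussian-smoothed over ~8
samples, tapered to zero at the endpoints, SD 1 mm). All 16 confederate
instances share one style; participants draw fresh styles. For the second
condition every underlying person's style is jittered once (CV 0.05), so
PG and WHP structure is correlated but not identical, which is what the
Mantel analysis needs.

What the generator does *not* emulate: biomechanical detail (fingers, grip
aperture), measurement artifacts (marker dropout, soft-tissue motion),
onset/offset detection error, and any motor-interference coupling between
the two actors. Note also that Procrustes scaling removes pure amplitude
differences entirely, and decile normalization removes pure duration —
styles are discriminated through duration's effect on the *relative*
magnitudes of WV/WA/WJ, through asymmetry and through curvature. Passing
tests on this generator therefore show that the machinery recovers planted
style structure under idealized reach kinematics, not that it handles every
failure mode of real recordings.

## Problem sizes and numerical choices

The validation suite and the acceptance script run the full study-sized
design (32 instances × 20 trials per condition). The subsampling robustness
analysis uses 100 resampling iterations per fraction in the acceptance
script and tests (the averaged-matrix ICC stabilizes well below that);
the pipeline default remains 1000. Monte-Carlo results always record their
seed and iteration count and are bit-reproducible given both. Tolerances:
shape degeneracy at centered sum of squares ≤ 1e-24; matrix symmetry
asserted at 1e-12; MDS convergence at relative stress decrease 1e-6.

## Known limitations

* One-pass alignment to a single target trial (no consensus iteration); the
  target-sensitivity analysis is the guardrail.
* The unstandardized variable space means the variable with the largest
  numeric range dominates the shape comparison; adding variables with very
  different scales changes the balance silently.
* No multiple-testing correction across the analyses; each permutation test
  is reported as-is.
* Nonmetric (ordinal) MDS and weighted-landmark Procrustes are out of scope.
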