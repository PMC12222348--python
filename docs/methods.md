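# Methods

## The measurement problem

Congruency tasks (flanker, Stroop, Simon) produce robust group-level effects
but notoriously unreliable individual-difference measures: the congruency
effect is a difference score, and when the congruent and incongruent
component scores are highly correlated across participants — as they are
whenever shared baseline speed dominates — most of the component variance
cancels out of the difference, leaving little true-score variance to
correlate across test halves. Reaching versions of these tasks decompose each
response into an initiation time (IT, stimulus onset to movement onset), a
movement time (MT, movement onset to response completion; RT = IT + MT) and a
reach-curvature measure (CURV), and the congruency effects on these kinematic
measures can carry more reliable individual differences than the classic
button-press RT effect. This package implements the full pipeline needed to
measure and evaluate that claim, plus a generative model under which the true
reliability is known exactly, so every stage is testable end to end without
any data download.

## Kinematic measures

Movement onset is the time of the first trajectory sample whose Euclidean
displacement from the start point exceeds a threshold (default 5 mm). A
displacement criterion was chosen over a velocity criterion because it is
robust to sampling noise and needs no differentiation; velocity-based onset
is out of scope. Raising the threshold can only delay the detected onset
(monotonicity, asserted as a property test).

CURV is the maximum deviation of the post-onset path from the direct path,
divided by the direct path length, where the direct path runs from the
position at movement onset to the selected-target contact. Deviation is
measured to the *infinite line* through those two points, not to the
segment; re-implementations using segment distance will differ on paths that
overshoot an endpoint. CURV is invariant under rigid motions and uniform
scaling of the trajectory (asserted as property tests). Both 2-D and 3-D
trajectories are supported.

For release-and-press interfaces (keyboard, touchscreen) IT and MT come from
key-release and key-press timestamps; no trajectory exists and CURV is
absent.

## Exclusion ladder

Trials are removed in a fixed order: (1) first trial of each block (no
previous-trial codes), (2) overt errors, (3) post-error trials (post-error
slowing), (4) absolute RT bounds — below 200 ms, or above 2500 ms for adults
/ 4000 ms for children, (5) a per-participant, per-congruency-condition rule
removing trials more than 3 SDs from that participant's mean RT, with the
mean and SD computed on the survivors of stages 1–4. Each removed trial is
attributed to the *first* rule that catches it, which keeps the exclusion
log additive (removed + retained = input, per participant). The SD rule uses
RT only and removes the whole trial from all measures. "Condition" for the
SD rule means the congruency level (within interface condition), not the
finer sequence cells. Post-error means following an *overt* error; trials
following excluded-but-correct trials are kept.

Filtering never alters measure values, only membership, and is idempotent on
the fixtures tested. (Strict idempotence is not a theorem: re-running the SD
stage on already-SD-filtered data recomputes a smaller SD and could in
principle catch a trial at the old boundary; in practice this does not occur
on the tested data and the property is asserted on fixtures.)

The optional log transform applies the natural log to the selected temporal
measures; congruency effects then become differences of log-means, i.e.
log response-speed ratios. The base is a convention — difference scores of
logged times are simply scaled by a constant under a base change.

## Split-half reliability

For each random split, every participant's retained trials are partitioned
within each congruency cell into halves of size floor(n/2) and ceil(n/2),
the extra trial (odd n) assigned to a random half so the halves stay
exchangeable. Half-wise scores — difference scores (mean incongruent minus
mean congruent) or single-condition component means — are correlated across
participants (Pearson), and the half-length r is corrected to full length
with Spearman–Brown, r_sb = 2r/(1+r). The reported estimate is the
arithmetic mean of r_sb over 5000 splits (correct-then-average; the
alternative, average-then-correct, differs only at second order and is not
used). The 95% interval is the 2.5th/97.5th percentile of the split
distribution. Splits are stratified by congruency only — difference scores
need balanced congruent/incongruent halves, and no finer stratification is
applied.

Splits with zero variance in a half, or r ≤ −1 (Spearman–Brown undefined),
are flagged invalid, excluded from aggregation and counted; more than 10%
invalid records a warning on the estimate. Participants with fewer than 2
retained trials in a required cell are dropped per measure and counted;
fewer than 3 eligible participants is an estimation error.

Qualitative labels use the conventional cutoffs on the estimate rounded to
two decimals: < 0.70 poor, 0.70–0.79 acceptable, 0.80–0.89 good, ≥ 0.90
excellent (0.90 itself labelled excellent).

A caution on the interval: the percentile-of-splits interval quantifies
split-to-split variability around this sample's estimate; it does not fully
capture participant-sampling variability, so its coverage of the true
(generative) reliability is expected to run somewhat below nominal —
observable in the null-configuration coverage checks, which require 9/10
rather than 95% coverage.

The analytic identity for difference-score reliability,

    r_dd = (r_xx s_x² + r_yy s_y² − 2 r_xy s_x s_y)
           / (s_x² + s_y² − 2 r_xy s_x s_y),

is implemented both as a pure function and as an end-to-end estimator whose
ingredients (component reliabilities via the permutation machinery, component
SDs, component correlation) are estimated from data; internal consistency
between the identity and the direct permutation difference-score estimate is
one of the acceptance checks.

Two implementations of the split coexist on purpose: a readable
single-split loop and a vectorized permutation engine. They are validated
against each other and against *exact enumeration* of the complete joint
split space at a size where that is possible (3 participants × 2 trials per
cell = 64 joint splits; at the 12-participant, 4-trials-per-cell scale the
joint space has 6^24 members and enumeration is impossible, so the engine is
instead checked against the independent loop estimator within Monte-Carlo
error).

## Sequence ANOVA

Cells cross trial-n congruency (C/I), trial-(n−1) congruency (c/i) and
response-repetition type. Cell means are unweighted (standard for
repeated-measures cell-means ANOVA); participants with an empty cell are
excluded listwise, with no imputation. Every effect in the 2×2×2
within-subject design is a single-df contrast over the eight cell means, so
F(1, N−1) = N·(mean contrast)²/var(contrast) — exact for two-level factors,
and cross-validated in the tests against statsmodels' general
repeated-measures ANOVA (all seven effects) and against pingouin on a
collapsed 2×2. No effect sizes beyond F and p are computed.

## Generative model

Per participant i, coefficients are drawn once from between-participant
normal distributions: IT baseline, MT baseline, an IT congruency effect a_i,
an IT previous-congruency effect b_i, an MT congruency effect c_i, and an MT
cI-r boost g_i. Per trial,

    IT = base_IT,i + a_i·[n = I] + b_i·[n−1 = I] + ε,   ε ~ N(0, σ_IT)
    MT = base_MT,i + c_i·[n = I] + g_i·[n = I ∧ n−1 = C ∧ repetition]
         + κ·f·[partial error] + ε′,                    ε′ ~ N(0, σ_MT)
    RT = IT + MT

with times truncated at 1 ms by resampling the noise. Each block holds equal
congruent/incongruent counts in random order; target sides are random, so
response repetitions arise naturally at ≈50% rather than being scheduled.
Overt errors flip the response side with a per-condition probability.
Partial errors occur with a per-condition probability; each has a commitment
fraction f ~ N(0.30, 0.10) truncated to (0, 1) — the fraction of the
movement initially headed at the wrong target — and adds a correction cost
κ·f to MT (κ = 100 ms at full commitment), encoding the idea that in-flight
corrections cost movement time, in the simplest testable form.

Normal coefficient and noise distributions are the simplest model matching
reported effect means/SDs; real RT distributions are right-skewed, and the
generator makes no attempt to reproduce skew, sequential autocorrelation
beyond the coded n−1 effects, fatigue/practice drift, or age-group
differences in partial-error rates. Passing tests therefore certify the
*pipeline arithmetic and estimator behaviour* under a known truth, not
distributional realism of any real dataset.

### Defaults

Study-condition defaults: 51 participants, 4 blocks × 48 trials
(keyboard-interface release-and-press design); IT congruency effect
30 ± 36 ms and MT congruency effect 56 ± 28 ms between participants
(keyboard-condition effect scale); overt-error probabilities 0.019
(incongruent) / 0.005 (congruent), giving ≈1.2% overall errors. Values no
published table pins down are package conventions, chosen once at realistic
magnitudes: baselines IT 350 ± 50 ms, MT 300 ± 60 ms; trial noise σ_IT = 60,
σ_MT = 80 ms; IT previous-congruency effect 15 ± 20 ms; MT cI-r boost
40 ± 25 ms; partial-error probabilities 0.15/0.03; geometry start (0, 0) mm
with targets (±100, 280) mm; sampling 100 Hz; onset jitter SD 0.5 mm. All
are configurable.

### True reliability

With between-participant effect variance τ² and trial-noise variance σ², the
full-length reliability of a difference score computed from n_C and n_I
retained trials is

    ρ = τ² / (τ² + σ²·(1/n_C + 1/n_I)),

the quantity the Spearman–Brown-corrected split-half estimator targets. For
RT, τ² and σ² are the sums of the IT and MT components (drawn
independently). The formula is exact only when the nuisance effects
(previous-trial congruency, cI-r boost, partial-error costs) are zero — they
otherwise add trial-level variance it does not model — so parameter-recovery
checks use configurations with the nuisance terms switched off.

### Trajectory synthesis

Clean reaches move at constant velocity from start to the selected target;
partial-error reaches head to the wrong target for the commitment fraction
of the movement, then straight to the selected target, so maximum lateral
deviation (hence CURV) grows monotonically with the commitment fraction.
Positional jitter is windowed to vanish at onset and contact, so the final
sample coincides exactly with the target. A constant-velocity profile (not
minimum-jerk) is used so that the 5 mm onset threshold is crossed within one
sample period at default speeds; the sample grid restarts at movement onset
for the same reason. The guarantee is sharp: extracted IT exceeds generating
IT by at most one sample period plus the threshold-crossing time (5 mm ÷
movement speed); at defaults that is one sample period for any movement
faster than 0.5 mm/ms, i.e. MT below ≈594 ms for the 297 mm default reach.

## Problem sizes in tests and the acceptance script

Checks are sized to be statistically decisive at desk scale, and sizes are
stated where they matter: parameter recovery uses 100 participants with ~80
retained trials per cell, averaged over 10 seeds against the closed-form
truth (tolerance ±0.05, the worked regime τ=36, σ=60 giving ρ = 0.935);
engine-vs-oracle checks use 5000 splits against exact enumeration (3 × 2
fixture) and a 3000-draw independent loop estimator (12 × 4 fixture);
sequence-pattern detection uses 10 seeds of the default 51-participant
design; ANOVA type-I calibration uses 200 null datasets of 24 participants
(binomial tolerance, 3 SE around 0.05). Permutation counts below 5000 are
used in some stochastic checks because the Monte-Carlo SE of a mean over
splits is an order of magnitude below the tolerances involved.

## Known limitations

- The percentile interval is a split-distribution interval, not a
  participant-sampling confidence interval (see above).
- The generator's normal, symmetric trial noise understates the skew and
  kurtosis typical of empirical congruency-effect distributions.
- The SD-rule/ordering conventions (survivor statistics, first-match
  attribution) are one defensible reading of common practice; pipelines
  making other choices will differ at the margin.
- Onset detection is threshold-based; very slow movements incur up to one
  extra sample of IT latency, and no velocity-based alternative is provided.
- The 2×2×2 ANOVA is a cell-means analysis; trial-level mixed models are out
  of scope.
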