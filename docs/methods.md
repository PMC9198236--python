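# Methods

## Generative observer model

A simulated participant represents a physical duration t as a Gaussian draw
with mean t and standard deviation w·t (scalar timing), truncated at zero by
resampling. The truncation is cosmetic: its probability mass is Φ(−1/w),
below 10⁻⁷ for any plausible w, so the closed-form (untruncated) moments and
psychometric function are used throughout the analysis.

On a 2IFC trial with intervals t₁ and t₂ the observer compares one percept
per interval and reports the larger; with probability λ (the lapse rate) it
instead guesses uniformly. The resulting probability of a correct response
at comparison offset Δt above a standard T is

    P(correct | Δt) = λ/2 + (1 − λ) · Φ( Δt / (w·√(T² + (T+Δt)²)) ),

which `observer.prob_correct_2ifc` evaluates and `observer.delta_at_accuracy`
inverts (Brent's method). When t₁ = t₂ no correct answer exists; correctness
is assigned at random with p = 0.5. This is a degenerate-input guard only:
the staircase's Δt floor is strictly positive, so ties never occur in a run.

Learning is an exponential decay of w over sessions,

    w(s) = w_∞ + (w₀ − w_∞) · exp(−s / τ),

applied per condition. Session s counts elapsed training: 0 at the pre-test
(and practice), k during training session k, and 5 at the post-test. Only
conditions configured to improve decay; all others hold w₀. By default the
EI group improves on empty-200 ms (trained) and filled-200 ms (same-duration
transfer) and the FI group improves nowhere — the qualitative group
structure this paradigm probes. τ = 0 is treated as the limit: w₀ at s = 0,
w_∞ afterwards.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| w₀ | 0.20 | baseline internal noise coefficient (≈ pre-training WF scale) |
| w_∞ | 0.13 | post-learning asymptote on improving conditions |
| τ | 1.5 sessions | learning time constant |
| λ | 0.02 | lapse rate |
| jitter CV | 0.10 | lognormal inter-individual spread of w₀ (plus 5% per-condition) |
| cohorts | 11 EI, 12 FI | analysis sample sizes of the emulated design |

With these values the expected trained-condition learning index is
(0.20 − 0.133)/0.20 ≈ 0.34. The defaults are fixtures chosen to produce a
realistic effect structure, not estimates of any human population. Note the
*measured* WF exceeds the internal w: the staircase tracks the 79.4%-correct
point, Δt*/T ≈ 1.3·w for this psychometric function (e.g. w = 0.20 measures
as WF ≈ 0.27).

Cohort generation draws one lognormal factor per observer (unit mean,
CV 0.10) scaling every condition's w₀, keeping the w₀:w_∞ ratio fixed so all
observers share the same fractional learning capacity. One seeded
`SeedSequence` per participant is split into per-block substreams, so any
block is independently reproducible.

## Staircase

One-up-three-down, 2IFC, 60 trials per block. Δt starts at 0.20·T; steps are
0.10·T until the third reversal is recorded and 0.05·T from the next change
onward (the change that causes the third reversal itself still uses the
coarse step — "after the third reversal" read as post-hoc). Standard and
comparison order is randomized per trial with p = 0.5.

Reversal bookkeeping: a reversal is the trial whose realized Δt change flips
the movement direction; no-change trials carry the previous direction, and
the first change only establishes one. The recorded reversal value is the Δt
presented on the flagged trial — the local extremum of the track. These
flags are recomputable from the Δt sequence alone (`recount_reversals`), and
a brute-force recount is the test oracle for the live state machine.

Numerical choices:

- **Δt floor** = one fine step (0.05·T, i.e. 10 ms at T = 200 ms). A zero Δt
  would make "correct" undefined; a floor of one fine step keeps the level
  grid regular. A clamped change that leaves Δt unchanged is not a realized
  movement and cannot be a reversal.
- An optional `frame_grid_ms` snaps Δt to a display-frame grid (10 ms on a
  100 Hz CRT); off by default.
- Responses are unspeeded and always recorded; no timeout path exists.

The equilibration point of the n-down-1-up rule is 0.5^(1/n) — 0.794 for
n = 3 (`convergence_probability`). Simulating lapse-free observers through
1,000-trial runs and evaluating the true psychometric function at the mean
late-reversal Δt reproduces this within a percentage point (measured ≈ 0.80;
the slight upward offset is the usual asymmetric-step-time bias of
reversal averaging).

## Threshold estimation and exclusion rules

- **Block**: mean of the reversal values excluding the first three; fewer
  than five reversals excludes the block. WF = threshold / T.
- **Training session**: the participant-session's block WFs pass a
  3-scaled-MAD screen (scale 1.4826) and survivors are averaged. The screen
  keeps x iff |x − center| ≤ 3·scaledMAD with no special case, so a fully
  constant session keeps everything while a constant majority keeps exactly
  the central values — the `isoutlier` convention. The center is the
  participant-session median by default; a MAD criterion needs a robust
  center and the unit being excluded is a block within one participant's
  session. `mad_center: group-mean` switches to the group-session mean for
  users who prefer the alternative reading. Exclusion only changes
  membership, never surviving values.
- **Participant**: per group and training session, a participant-session is
  flagged when its WF exceeds the group mean by 3 sample SDs (zero-SD
  sessions flag nothing); more than one flagged session excludes the
  participant. Applied once, on training-session WFs only, before any
  learning analysis — the pre/post tests are the measured outcome.

Estimator calibration (see `analysis/04_convergence.py`): over 200 simulated
60-trial blocks the mean block threshold recovers the observer's true
79.4% point within a few percent for w between 0.16 and 0.25, and within
about +10% at w = 0.12. Below w ≈ 0.10 the fine step becomes coarse relative
to the threshold and the reversal mean acquires a >15% upward discretization
bias; this is a property of the 60-trial protocol, and a known limitation of
applying it to very sensitive observers.

## Learning analysis

LI = (pre − post)/pre per condition, computed from the single pre and post
block of that condition (no pooling); scale-invariant by construction. A
*learner* shows a strict decrease on the trained condition — ties classify
as non-learner ("decreased" read strictly). The learner definition is tied
to the trained condition by default and is configurable. Group summaries
report mean LI, between-subject SEM (SD/√n) and n per group × condition
cell; cells with n < 2 are flagged rather than given an SEM. Statistical
inference (ANOVAs, corrected t-tests, Bayes factors) is deliberately out of
scope: the exported tidy tables are ready for any standard statistics
package.

Because the pre-test WF sits in the denominator and is estimated from a
single 60-trial block, LI is a ratio statistic with a negative bias of order
CV² (≈ −0.05 to −0.1 here). Cells with no true learning therefore scatter
slightly below zero; "no effect" should be read as *indistinguishable from
zero* given the between-subject SEM, which is how the end-to-end structural
test evaluates the FI cells.

## What the simulation does and does not emulate

The generator reproduces the design's structure — schedule (10 practice +
240 pre + 2,880 training + 240 post trials per participant), staircase
protocol, condition-specific sensitivity, session-wise learning with
cross-format transfer, inter-individual variability, lapses. It does not
model format-specific perceptual mechanisms (an "empty" and a "filled"
condition differ only by their configured noise trajectories), the filled
duration illusion, reaction times, session-to-session drift other than
learning, or floor effects tied to baseline sensitivity. Passing end-to-end
tests therefore shows that the measurement chain faithfully recovers the
structure the generative model encodes — not that human data would show
that structure.

## Problem sizes

Test and analysis runs use the study's native sizes (60-trial blocks, 11/12
observer cohorts, full 5-day schedule — about 78k trials end-to-end, a few
seconds of compute); calibration checks use 100–500 replicate blocks or
1,000-trial runs, chosen to make Monte-Carlo error small relative to the
tolerances being checked.
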