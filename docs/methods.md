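# Methods

## Task model

The task interleaves two independent two-armed bandits ("self" and
"other" reward conditions) within each block, strictly alternating and
starting with "self". Each bandit has one arm rewarding at `p_high`
(default 0.70) and one at `p_low` (default 0.30); which arm carries
`p_high` swaps after every `reversal_period` presentations of that
condition (default 10). Arms reward independently: each choice draws a
Bernoulli outcome from the chosen arm's current probability. Defaults:
3 blocks of 30 trials per condition (60 per block), a 4-second response
window kept as metadata only. The schedule itself is deterministic —
condition order and reversal times carry no randomness — so simulations
resample only choices and rewards.

The per-block trial count and the reversal timing are design choices:
30 trials per condition keeps maximum-likelihood fitting feasible per
block, and the fixed 10-trial reversal period creates the rapid-reversal
regime in which learning rate, rather than choice stochasticity, limits
performance. Both are configurable, and the grid correlations below are
sensitive to them (see Limitations).

## Learning models and likelihood

Choice follows a softmax on the value difference, P(a) =
logistic(τ·(V_a − V_b)), computed in shift-invariant form so that
arbitrarily large |τ·ΔV| cannot overflow. Values update by the delta
rule for the chosen arm only. Both conditions keep their own value pair
(each condition has its own stimulus pair); M1 ties (α, τ) across
conditions, M2 gives each condition its own (α, τ) and therefore has a
likelihood that decouples across conditions; M0 fixes P = 0.5.

Values are initialised at v0 = 0.5 for both arms, the uninformative
midpoint of the {0, 1} reward scale, and reset at block boundaries
(fitting is per block). Missed responses contribute nothing to the
likelihood and trigger no value update. The negative log-likelihood sums
−log P(observed choice) over non-missing trials; a sequence with no
scored trial has no likelihood and is rejected.

## Fitting

Per subject and block, each model is fitted by maximum likelihood over
the box α ∈ [0, 1], τ ∈ [0, 20]. The τ ceiling reflects that beyond ~20
the policy is effectively greedy and the likelihood flat. The optimizer
is deterministic: the NLL is evaluated on a fixed start grid
(α ∈ {0.1,…,0.9} × τ ∈ {0.5, 1, 3, 5, 10}, vectorised over starts), the
best three starts are refined by a nested local grid search (two rounds
of a 9×9 box shrinking 4× per round), and the winner is polished with
bounded L-BFGS-B. A reduced profile (`FAST_FIT_SETTINGS`: 3×3 starts,
one refinement, no polish) serves replicated simulation studies; on test
instances the full profile matches an exhaustive 101×161 grid search in
296 of 300 condition-fits and is never more than ~1e−3 NLL worse.

M2 is fitted per condition (two 2-parameter problems); its BIC uses
k = 4 and n = all non-missing trials entering the block likelihood.
BIC = k·ln(n) + 2·NLL, summed across subjects within a block for
cohort-level comparison (fixed-effects aggregation); ΔBIC is reported
relative to the winning model.

Exclusions mirror the study design: any block with more than half the
responses missing, or a block-1 fitted α_self at zero (≤ 1e−6 — no
evidence of learning even for one's own reward, making the baseline
categorization meaningless).

## Posterior predictive check and parameter grid

The PPC re-simulates each subject 1,000 times with their fitted block-1
M2 parameters on the same schedule and compares the mean simulated
high-reward-probability choice rate (HRP) per condition with the
observed one. The grid study simulates the model at every (α, τ) in
{0.1,…,1.0 step 0.1} × {0.5,…,10.0 step 0.5} (200 cells, 1,000 agents
per cell, independent seed substreams per cell) and correlates cell α
and cell τ with cell mean HRP across cells.

Under the default schedule the learning rate clearly dominates
(r_α ≈ 0.73 vs r_τ ≈ 0.53, seed-stable to ±0.01), and HRP is
non-decreasing in α along every τ ≥ 2 row. Both correlations move with
the reversal schedule: faster reversals (every 5 trials) sharpen the
ordering to r_α ≈ 0.92, r_τ ≈ 0.17, while a single mid-block reversal
reverses it (τ dominates). The rapid-reversal surface also compresses
expected HRP into roughly 0.50–0.65, which matters for the PPC: across
agents with α ~ U(0.1, 0.9), τ ~ U(1, 8), the spread of *expected* HRP
(sd ≈ 0.05) is below the 30-trial binomial noise of observed HRP
(sd ≈ 0.08), so the observed-vs-predicted correlation is attenuated to
≈ 0.33 even though the predicted HRP tracks the generating parameters'
expected HRP at r ≈ 0.80. The self-consistency tests assert the latter,
which is what the check validates (parameter estimation), and only a
positive lower bound for the former.

## Synthetic cohorts

The generator emulates the statistical structure the group analysis
assumes. Each subject: group OBS (n = 49) or CON (n = 53); latent
subtype selfish with probability 0.64, else prosocial. True per-block M2
parameters are drawn from truncated normals (α on [0, 1], sd 0.15; τ on
[0.1, 15], sd 1.5) around subtype means — selfish: α_self 0.55, α_other
0.28; prosocial: α_self 0.35, α_other 0.50; τ_self 4.0, τ_other 3.5 for
both (subjects learn better and faster for themselves). The block-1 draw
is rejection-sampled to keep the subtype's PLS sign well-defined. Block
2 shifts the learning-rate means in the observation group only —
selfish: Δα_other = +0.25, Δα_self = −0.15; prosocial: Δα_self = +0.08 —
and block 3 reuses the block-1 parameters (observation removed).
Behavior is forward-simulated with the M2 model on the task schedule;
reaction times are lognormal (median 700 ms "self", 780 ms "other",
σ = 0.25 — cosmetic, to exercise the z-RT pipeline); responses go
missing independently at rate 0.01. Everything derives from one seed.

What the generator does **not** emulate: sequential dependencies beyond
the delta rule (win-stay biases, perseveration kernels), RT–difficulty
coupling, learning across blocks, or drop-out. Passing tests therefore
show that the pipeline recovers what this generative family plants, not
that real behavior follows the model.

## Group statistics

Subject summaries carry HRP, z-scored RT (z within subject within block
across all non-missing trials, then averaged per condition; zero-variance
blocks yield zeros with a flag), fitted (α, τ) per condition, and PLS
per block. The label is fixed by block-1 PLS: Selfish iff PLS < 0 (a
PLS of exactly 0 is Prosocial).

The mixed ANOVA takes a long table with arbitrary between- and
within-subject factors. Within effects are formed by orthonormal
contrast transforms of the repeated measures; every effect is tested by
Type III sums of squares of the effects-coded between design applied to
the transformed columns, pooled across columns (the univariate,
sphericity-assumed analysis; no Greenhouse–Geisser correction, matching
the integer error df of the target design — e.g. (N − 4)·2 = 196 error
df for the 4-way interaction at N = 102). The implementation agrees with
R `car::Anova(type = 3)` to printed precision on unbalanced 2×2 × 3×2
designs, with pingouin on the coding-invariant rows of 1×1 designs, and
with a brute-force contrast-score decomposition on balanced all-2-level
designs to 1e−8. Degenerate inputs (zero error variance, between cells
with fewer than two subjects, unbalanced within cells) are flagged or
rejected with the offending subjects named.

Post-hoc block-1→2 paired t-tests are BH-FDR-adjusted within the family
of four contrasts {self, other} × {Selfish, Prosocial} inside one
observation arm — the focused family matching the omnibus interaction;
the control arm is reported alongside as its own family. The bootstrap
robustness check resamples each group 1,000 times (percentile CI;
two-sided p as twice the smaller tail fraction against zero). All tests
are two-sided at α = 0.05.

Because labels come from fitted block-1 PLS, within-cell block-1→2
contrasts inherit a regression-to-the-mean component (subjects labelled
Selfish partly by estimation noise drift back toward the mean in block
2). This is visible in the control arm of the worked example and is a
property of the categorize-then-test design itself; the group × label
comparisons are unaffected because both arms share the selection.

## Calibration and power

With no planted shifts, the 4-way interaction rejects at the nominal
rate (measured 3–7% over 200 replicate cohorts of 16 + 16 subjects,
within binomial tolerance of 5%). With the planted shifts, the focused
FDR post-hoc flags the α_other increase in essentially every full-size
replicate, but the 4-way omnibus reaches significance in only ~10% of
them: at 30 trials per condition the MLE noise on α (error sd ≈ 0.25,
true-vs-fitted r ≈ 0.6 — an information limit, not an optimizer defect:
exhaustive grid search does no better) plus ~22% label misclassification
swamps the diffuse omnibus contrast, while the same analysis on the true
generating α rejects in 100% of replicates. Power for the omnibus would
require more trials per condition; the focused contrast does not.

Problem sizes used by the replicated studies: 200 null cohorts of
16 + 16 subjects with the reduced fit profile, 20 effect cohorts of
49 + 53 subjects; parameter recovery uses 200 agents (α ~ U(0.1, 0.9),
τ ~ U(1, 8), one 30-trial-per-condition block).

## Numerical and design choices

* Log-likelihoods via `log1p`/`logaddexp`; no overflow for |τ·ΔV| ≤ 1e4.
* Seed discipline: one global seed; each pipeline stage derives a
  substream as `SeedSequence([seed, crc32(stage_name)])`; grid cells and
  PPC subjects spawn children from their stage stream. Derived seeds are
  recorded in the run provenance file.
* CSV: comma-separated UTF-8, "NA" for missing, 1-based block/trial
  indices; floats written as `%.17g` and parsed with round-trip
  precision so write→read is exact.
* Ties: a block-1 PLS of exactly 0 labels Prosocial; softmax ties give
  P = 0.5; the BH adjustment uses the standard step-up with ties shared.
* The trial-table reader validates schema, enum values, NA-consistency
  and (subject, block, trial) uniqueness, reporting 1-based row numbers.

## Known limitations

* The reversal schedule and per-block trial counts of the original task
  design are not pinned by any distributed data; the grid correlations
  (and with them the α-vs-τ margin) depend on them strongly, as the
  sensitivity sweep in `analysis/03_model_validation.py` shows.
* Maximum-likelihood estimates of α from 30 trials are noisy (r ≈ 0.6
  against truth) and τ estimates pile at the upper bound for
  near-greedy short sequences; hierarchical or MAP estimation would
  shrink both but is outside the scope of this (deliberately MLE-based)
  pipeline.
* With 60 trials per block, BIC prefers the shared-parameter model M1
  unless the conditions separate in both α and τ; the condition-separate
  model wins the comparison only for strongly differentiated cohorts.
* The ANOVA is sphericity-assumed by design; a Greenhouse–Geisser
  option would change the 3-level block effects slightly.
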