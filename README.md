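# prlearn — prosocial reinforcement learning on a reversal bandit

People learn to earn rewards not only for themselves but also for others,
and the two can be learned at different rates. `prlearn` implements the
full computational pipeline for studying that asymmetry — and how it shifts
when people believe they are being watched — on the **prosocial reversal
learning task**: two interleaved two-armed bandits, one whose points go to
the participant ("self" condition), one whose points go to another person
("other" condition). Within each bandit one arm rewards with probability
0.70 and the other with 0.30, and the assignment reverses during the task.

The behavioral model is a Rescorla–Wagner learner with a softmax policy.
On trial *t* the probability of choosing option *a* is

    P(t, a) = 1 / (1 + exp(−τ · (V(t,a) − V(t,b))))

and only the chosen option's value is updated by the reward prediction
error,

    V(t+1, chosen) = V(t, chosen) + α · (R(t) − V(t, chosen)),

with reward R ∈ {0, 1}, learning rate α ∈ [0, 1], and inverse temperature
τ ≥ 0. Three models are fitted per subject and block by maximum
likelihood and compared by BIC = k·ln(n) + 2·NLL:

* **M0** — random choice, P = 0.5 (null);
* **M1** — one (α, τ) shared by both reward conditions;
* **M2** — condition-specific (α_self, α_other, τ_self, τ_other).

From the condition-separate fits the pipeline computes each subject's
**prosocial learning sensitivity**, PLS = α_other − α_self, labels
subjects *Selfish* (baseline PLS < 0) or *Prosocial* (PLS ≥ 0), and runs
the group statistics: manipulation checks, 3-way (Group × Block × Reward)
and 4-way (Group × PLS group × Block × Reward) mixed repeated-measures
ANOVAs on the learning rates, Benjamini–Hochberg FDR post-hocs, and a
percentile bootstrap. Because no participant-level data are distributed,
a synthetic-cohort generator produces trial-level datasets with the same
structure (group sizes 49/53, ~64% selfish at baseline, block-2
learning-rate shifts under observation) so that every stage of the
analysis is testable end to end.

The mixed ANOVA is implemented here (orthonormal within-subject contrasts
plus Type III effects-coded between-subject tests — the SPSS-style
univariate sphericity-assumed analysis, verified against R's
`car::Anova`), since no installed Python package handles two between- and
two within-subject factors.

## Worked example

The numbered scripts under `analysis/` run the study pipeline on a
synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_fit_models.py
python analysis/03_model_validation.py --seed 1
python analysis/04_group_statistics.py --seed 1
```

With seed 1 this prints, among other lines:

```
simulated 102 subjects (49 OBS / 53 CON), 66/102 selfish at baseline
block 1: winner M1; summed BIC M0=8398.2, M1=7350.9, M2=7719.1
100 subjects retained, 2 excluded
grid (reversal every 10): r(alpha, HRP) = 0.727, r(tau, HRP) = 0.521 -> learning rate dominates
4way ANOVA, group x pls_group x block x reward: F(2,192) = 2.485, p = 0.0860
OBS   OBS-Selfish other: block1 vs block2 -5.097650 0.000018 0.000071
bootstrap (Prosocial alpha_self change, OBS-CON): diff = -0.145, 95% CI [-0.436, 0.141], p = 0.306
```

Reading the output: about two thirds of simulated subjects learn faster
for themselves at baseline; the grid study shows that the learning rate,
not the inverse temperature, predicts how often agents pick the
currently-better arm under rapid reversals (r = 0.73 vs 0.52); and the
planted observation effect surfaces most clearly in the focused post-hoc —
the Selfish observation-group subjects' α_other rises from block 1 to
block 2 (t = −5.10, FDR-adjusted p < 0.001) — while the 4-way omnibus
interaction is diluted by estimation noise at 30 trials per condition
(see `docs/methods.md` for the power analysis behind this).

The single-command equivalent is the library call
`prlearn.run_pipeline(RunConfig(seed=1))`, which chains every stage and
writes all artifacts with full seed provenance.

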