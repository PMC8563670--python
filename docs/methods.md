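# Methods

## The task

The two-step task is a sequential decision paradigm designed to dissociate
two modes of control. On each trial the subject chooses between two
first-stage stimuli ("rockets", coded 1 and 2). Rocket 1 leads to
second-stage state A with probability `p_common = 0.70` (a *common*
transition) and to state B otherwise (*rare*); rocket 2 mirrors this. Each
second-stage state offers a choice between two stimuli ("aliens": state A
holds {3, 4}, state B holds {5, 6}), each paying one point with a
probability that drifts across trials as a Gaussian random walk (step SD
0.025) reflected into [0.25, 0.75]. A session has 201 trials in three
blocks of 67; block breaks carry no computational consequence here — the
walk and all learning state continue across them. Trials without a response
are *missed*: they hold no choices or reward, contribute to no likelihood
or stay statistic, and leave all learning state untouched.

Implementation notes for the environment:

- The reflected walk is computed by folding the free (unreflected)
  cumulative walk back into the interval. Folding equals per-step
  reflection up to sign flips of later steps, so the two constructions are
  equal in law; folding vectorizes. Starting values are independent uniform
  draws within the bounds.
- The rocket-to-dominant-state mapping (1 -> A, 2 -> B) is a fixed
  convention; on-screen counterbalancing is presentation-level and ignored.

## The agent

Behavior is modeled by a seven-parameter hybrid learner.

Model-free values of the two rockets update only for the chosen rocket,
using two prediction errors both computed before any update on the trial:

    Q_mf <- Q_mf + alpha1 (Q_s2 - Q_mf) + alpha21 (r - Q_s2)

where `Q_s2` is the pre-update value of the chosen second-stage stimulus.
`alpha1` in [0,1] scales the state-transition error; `alpha21` in [0,1]
scales the eligibility-trace contribution of the second-stage reward
prediction error (equivalent to `alpha1 * lambda` in the classic
single-learning-rate parameterization — the product form trades off the two
rates, so the separated form is used throughout). Model-based values are
computed prospectively from the *true* transition probabilities (not
learned):

    Q_mb(1) = 0.7 max(Q3, Q4) + 0.3 max(Q5, Q6)     (rocket 2 symmetric)

The systems combine additively, `Q_h = beta_mb Q_mb + beta_mf Q_mf` with
non-negative weights, and the first-stage choice is logistic in
`(Q_h(1) - Q_h(2)) + pi * C`. `C` is a signed perseveration indicator: +1
if the previous completed first-stage choice was rocket 1, -1 if rocket 2,
0 before the first completed trial. The signed (+/-1) coding is the unique
two-option reduction of "repeat the previous choice" to a single additive
term; note the absolute scale of fitted `pi` depends on this coding (0/1
coding would double it). Perseveration is stimulus-based, not
key/position-based. Second-stage values follow a delta rule
`Q_s2 <- Q_s2 + alpha2 (r - Q_s2)`, and second-stage choices are logistic
with inverse temperature `beta2 >= 0`. Note there is no separate inverse
temperature at stage 1: the weights `beta_mb`, `beta_mf` carry the scaling.

All Q values initialize at 0.5, the midpoint of the reward-probability
range (configurable). The session log-likelihood sums
`log P(choice1) + log P(choice2)` over completed trials under the
sequential recursion above; missed trials contribute zero and do not move
the perseveration reference. The trial loop is JIT-compiled (numba); the
readable step functions are the reference implementation and the test suite
asserts exact agreement between the two routes.

## Stay-switch statistics

Trial *t* (t >= 2) is classified by trial *t-1*'s transition-by-reward cell
(CR, RR, CU, RU) and whether the first-stage choice repeated. Pairs
containing a missed trial are dropped — the paradigm excludes aborted
trials, and the following trial's "previous trial" is then undefined; this
exclusion rule is a declared choice. Consecutive pairs spanning a block
break are retained. Per cell, the stay probability is stays / pairs; the
two strategy indices are

    MF = (P(stay|CR) + P(stay|RR)) - (P(stay|CU) + P(stay|RU))
    MB = (P(stay|CR) + P(stay|RU)) - (P(stay|CU) + P(stay|RR))

a reward main effect and a reward-by-transition crossover respectively.
Group tests: classical paired t (with Cohen's d = mean/SD of differences
and a t-quantile 95% CI), and a 2x2x2 repeated-measures ANOVA
(condition x transition x reward) computed as one-sample t-tests on +/-1
contrasts of the eight cell means per subject — with two-level factors
every RM-ANOVA F equals the squared paired t on the corresponding
contrast (F = t^2, df = (1, n-1), partial eta^2 = t^2/(t^2 + df)). ANOVA
p values are reported uncorrected; Bonferroni correction is reserved for
the seven model-parameter tests.

## Hierarchical fitting

Parameters live on two scales. The population model and all group tests use
the *transformed* (unconstrained, "Gaussian") scale: logit for the three
learning rates, natural log for the three non-negative weights, identity
for `pi`. Values at the closed boundary are clipped inward by 1e-6 with a
warning before transforming.

Fitting is empirical-Bayes EM:

1. *Initialization.* Every subject-condition is fit by unregularized
   maximum likelihood (Nelder-Mead on the transformed scale, 10 restarts
   drawn from a broad seeded start distribution, objective tolerance 1e-6,
   at most 2,000 evaluations per restart; transformed values are clipped to
   +/-20 inside the objective to keep the likelihood finite). The prior
   mean and variance are set to the pooled moments of these ML estimates
   across all subjects and conditions.
2. *EM under one shared population prior.* E-step: each subject-condition's
   MAP estimate under the current independent-Gaussian prior, warm-started
   at the previous estimate plus fresh prior draws. M-step: the prior mean
   is the mean of all MAP estimates (both conditions pooled); the prior
   variance is the mean of squared deviations *plus* each subject's
   diagonal Laplace (inverse-Hessian, central finite differences)
   posterior variance, floored at 1e-4. The curvature term is essential:
   with point estimates alone the shrinkage feeds back into the M-step and
   the population variance collapses geometrically toward the floor, which
   degrades and correlates all subject estimates. Iteration stops when no
   prior mean moves more than 1e-3, or when the Laplace-approximate
   marginal likelihood — the objective EM ascends — improves by less than
   2 nats (improvements that small are within restart noise; for weakly
   informed parameters such as `alpha21` the population variance is a
   nearly flat direction of this objective and would otherwise keep
   drifting toward zero long after the objective has plateaued,
   over-shrinking every subject), or after 100 rounds. A final E-step
   re-fits every subject under the converged prior.

   The prior is deliberately *shared across conditions* (it models the
   parameter distribution of the overall population) even though MAP
   estimates are obtained per condition. Estimating a separate prior per
   condition is tempting but statistically unsound for the paired tests
   downstream: the chance difference between the two estimated prior means
   enters every subject's paired difference as a constant shift — raising
   mean(diff) without raising sd(diff) — so the paired t inflates as
   shrinkage grows (on strict-null synthetic cohorts this produced
   spuriously Bonferroni-significant parameters in about half the
   replicates). Shrinkage toward a single shared mean instead scales all
   paired differences by a common factor, and the t statistic is invariant
   to that scaling, so type-I control is preserved.

Per-subject restart seeds derive from the master seed and a stable hash of
the subject/condition label, so fits are deterministic and invariant to
session ordering. Fits that converge on no restart are flagged, not
raised; estimates that hit the transform clipping are flagged as degenerate.

Condition comparisons are paired t-tests per transformed parameter with
Bonferroni correction (p_corrected = min(1, 7p)). Model comparison with the
condition factor included (one parameter set per subject-condition) versus
excluded (one set per subject, both conditions fit jointly) uses
AIC = 2k - 2 lnL, with each subject's likelihood evaluated at its MAP point
without the prior term and k = 7 per fitted set; the reported delta is
AIC(without) - AIC(with), positive when the factor earns its parameters.

## Synthetic cohorts

The cohort generator emulates the paired study design: 32 subjects by
default, two conditions (sated baseline, hungry), one 201-trial session per
condition with an independent reward walk, and missed trials injected
independently per trial at rate 2.3/201. Subject parameters are drawn on
the transformed scale from independent Gaussians (baseline native values
near alpha = 0.5, beta = 3, pi = 0.2; SD 0.5 — typical of two-step
cohorts). The population SD splits between a stable subject-level and a
condition-level component (`condition_var_frac`, default one half each);
the hungry condition's means are shifted by `d * sqrt(2 frac) * sd`, so the
paired Cohen's d of the ground truth equals the declared d exactly in
expectation (defaults: d = 0.76 on alpha1's transform, d = 0.52 on
alpha21's, zero elsewhere). `condition_var_frac = 0` gives a strict null
(identical parameters across conditions), which is the right null for AIC
comparisons — under the paired-d design, a zero *mean* effect still leaves
real per-condition parameter deviations that the with-factor model
legitimately fits.

What the generator does *not* emulate: reaction times, hunger/mood ratings,
training effects, demographic covariates, any drift of parameters within a
session, and position-based response biases. Passing tests therefore
validate the estimation and analysis machinery under the model's own
assumptions, not the model's adequacy for real subjects.

## Parameter recovery

Recovery draws parameter sets from the declared generating distribution,
simulates two 201-trial sessions per synthetic subject, refits with the
full hierarchical procedure, and correlates generating against recovered
values per parameter on the transformed scale. The generating draws are
whitened by default: the empirical cross-correlations between generating
parameters are made exactly zero and the empirical SDs exactly match the
declared ones. Rationale: the off-diagonal summary exists to measure
correlations *introduced by the fitting procedure*, and the chance
correlation of independent draws (SD about 1/sqrt(n), about 0.18 at
n = 32, with extremes near 0.4) would confound it at this sample size.
Whitening removes the confound by design rather than by seed selection.
The cohort generator keeps plain independent draws.

Reported summaries: the 7x7 cross-correlation matrix, its diagonal
(minimum and maximum), and the maximum absolute off-diagonal entry.

## Problem sizes and numerical choices

- Default fitting options (10 restarts, 2 EM draws, 100 max EM rounds) are
  used for the headline 32-subject recovery study. Replicate-cohort
  checks (type-I control across 20 null cohorts of 16 subjects; power
  across 5 effect cohorts of 32 subjects) use lighter options (3-4
  restarts, 1 EM draw, 10-15 EM rounds), chosen as the smallest settings
  at which single-cohort fits are stable; these are replicate studies, so
  what matters is the across-cohort rate, not per-fit polish.
- Nelder-Mead tolerances: fatol 1e-6, xatol 1e-4. Likelihood guard: any
  non-finite objective evaluates to +1e100.
- Ties and degenerate inputs: empty stay cells yield NaN probabilities and
  an explicit error from the index contrasts; zero-variance paired
  differences raise a degenerate-input error (identical samples return
  t = 0, p = 1); subjects missing a condition are dropped with a warning.

## Known limitations

- The likelihood treats the transition structure as known and fixed; early
  trials where a real subject is still learning the structure are
  mis-modeled.
- Diagonal Laplace curvature ignores posterior parameter correlations
  within subject; the population model is likewise independent per
  parameter.
- AIC bookkeeping (ML-at-MAP likelihoods, k = 7 per set) is one declared
  convention among several defensible ones; absolute delta values should
  be compared only within this convention.
- `alpha21` is the least identifiable parameter at 201-trial sessions; its
  subject-level estimates are noticeably shrunk and its recovery
  correlation is the lowest of the seven.
- Condition effects planted on the latent (ground-truth) scale attenuate
  substantially in the fitted parameters: at one 201-trial session per
  condition the per-subject estimation noise of a learning-rate transform
  is comparable to the true between-condition spread, so the paired
  Cohen's d measured on MAP estimates runs at roughly half the latent d or
  less. Power calculations for the seven Bonferroni-corrected parameter
  tests should be based on the attenuated, not the latent, effect size.
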