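# Methods

## The decision models

Two team members work toward a shared deadline and interact only through
interruptions. At a decision point the *interrupter* weighs the benefit `b` of
interrupting against the cost `c` to the *interruptee*; the *interruptee*
weighs the same quantities when deciding whether to accept. With task
importance held constant, benefit and cost are carried entirely by **time
pressure**

    TP = TR / TA = (tasks remaining x time per task) / (time available),

the ratio of the time required to clear all outstanding work to the time left
before the deadline (TP > 1 means overloaded). Time pressure is undefined once
the deadline has passed; such decisions are removed before fitting.

Both decision types are Bernoulli choices with logistic probabilities.

**Monotonic family.** The interrupt probability for subject *i* is
`logistic(alpha_i + beta_i (b - c))` with `b` the interrupter's TP and `c` the
interruptee's; the accept probability is `logistic(gamma_i + delta_i (b - c))`
with the same role convention (benefit tracks the interrupter's pressure).
Bias above zero means a tendency to interrupt (or accept) when benefit equals
cost; sensitivity weights the difference. The probability is strictly
increasing in `b - c`.

**Non-monotonic family.** Benefit and cost are quadratic in each side's time
pressure — for interrupt decisions `b = tau_i TP_self + omega_i TP_self^2` and
`c` the same polynomial in the other's TP; for accept decisions the
coefficients are `kappa_i`, `lambda_i` with benefit driven by the coworker's
(interrupter's) TP. The difference `b - c` enters the log-odds with a unit
coefficient, `logistic(bias + (b - c))`, so the sensitivities live inside the
polynomial. With a negative quadratic coefficient the effect of time pressure
is an inverted U peaking at `-tau/(2*omega)`; with the quadratic coefficient
at zero the family reduces exactly to the monotonic one. The discriminating
property is translation invariance: adding a constant to both TPs leaves
monotonic probabilities unchanged but moves non-monotonic ones whenever the
TPs differ.

The printed form of these models omits the logistic denominator; they are
implemented as the standard logistic `1/(1+exp(-x))`, the only reading under
which outputs are probabilities and positive bias means a tendency to act.

**Time-pressure convention.** `TR` uses a configurable `time_per_task`
(default 11 s, the design's service time). The fitted statistic is sometimes
expressed as tasks-remaining over time-available; the two differ by the
constant `time_per_task`, which is absorbed into the sensitivities, so either
convention is reproducible. The convention used is recorded in the model spec.
Task importance, held at its medium level (5) in the design, is absorbed into
the sensitivities as well and is not a free variable here.

## The task simulator

The simulator reproduces the two-nurse ICU-discharge paradigm: each nurse
discharges two patients, each requiring a vitals task (13 questions), a
medication task (16) and a documentation task (24), i.e. 106 questions per
nurse. Deadlines are 960, 1320 or 1680 s; a detected error costs 3 or 6 s
(the error-impact manipulation). The simulated coworker answers a question
every 11 s with a 5% error rate and responds to interruptions with the
monotonic accept rule at bias 0 and sensitivity 1 — exactly the policy the
human participants faced. The participant role is played by a configurable
policy agent (model family + subject parameters, service time, error rate).

At scheduled question indices an agent must resolve an interruption prompt
before progressing: it decides to interrupt or to change patients. An accepted
interruption pauses the interruptee for one service time, clears the
interrupter's prompt, and puts the interruptee at elevated error risk for the
next eight answered questions (risk multiplier configurable, default 2.0). A
rejected interruption lets the interruptee continue while the interrupter
switches to the other patient if that patient is not itself blocked on a
prompt, otherwise retries every 11 s. Questions are abandoned after three
failed attempts. The block ends when both nurses have completed all questions;
a hard wall-clock cap guards pathological policies (e.g. an accept-never
coworker facing an interrupt-always participant) and flags the log as
truncated rather than failing silently.

Design choices worth noting:

- **Prompt schedule.** The original design varied prompt timing across tasks
  without publishing it; the default places two evenly spaced prompts per task
  (configurable per-task index lists), recorded in the config for
  reproducibility.
- **Clocks.** Each nurse has its own `time_used`; decision probabilities are
  evaluated at the deciding agent's clock and the log is ordered by clock with
  a participant-before-coworker tie-break. Decisions themselves take no task
  time; retry spacing (11 s) is the only waiting cost.
- **Post-deadline decisions.** Participants in the experiment could continue
  past the deadline, and those decisions were excluded from analysis. The
  simulator likewise keeps running: a prompt occurring with `time_available <=
  0` is decided with the time available clamped to 1 s (extreme pressure) and
  the event is emitted with its true non-positive `time_available`, so the
  preprocessing filter removes it exactly as the behavioral exclusions were.
- **Coworker interrupt policy.** Only the coworker's *response* policy is
  documented by the design; its interrupt-side parameters default to the same
  neutral bias 0 / sensitivity 1 by analogy and are configurable.
- One shared RNG stream per block, seeded from the run seed, consumed in
  simulation order: identical seeds give byte-identical logs.

## Synthetic data

The behavioral dataset is not distributed with this package; all estimation
machinery is validated on synthetic cohorts with known truth. Subject
parameters are drawn from untruncated Normal population distributions (the
standard hierarchical-logistic convention); decision contexts come either from
the simulator or from a direct law — independent uniform time pressure on
[0.2, 2.0] per role, spanning clearly under- to over-loaded while keeping TP
defined. Outcomes are Bernoulli draws from the chosen family. Direct-mode
rows carry round-robin block/deadline/error-impact labels and a constant
positive `time_available` so they pass the same schema validation as real
tables; these fields are inert for fitting.

What the generator does *not* emulate: learning or fatigue across blocks,
inattention, response-time variation beyond an optional lognormal service
time, or any dependence of decision parameters on the deadline/error-impact
conditions. Passing recovery tests therefore demonstrate that the estimation
machinery is correct and well calibrated under the models' own assumptions,
not that the models describe human behavior.

## Hierarchical estimation

Each candidate model (monotonic/non-monotonic x interrupt/respond) is a
hierarchical logistic model: subject coefficient vectors `theta_i ~
Normal(mu, diag(sigma^2))`, outcomes Bernoulli with the family's choice
probability. Priors are weakly informative on the logit scale where TP spans
roughly [0, 2]: `mu ~ Normal(0, 2)` and `sigma ~ Half-Normal(1)`. Under these
priors the prior-predictive choice rate spans essentially (0, 1), checked in
the test suite. Sensitivities are not sign-constrained.

Sampling uses an adaptive Hamiltonian Monte Carlo sampler written for this
package (the models' log-posteriors have cheap closed-form gradients): dual
averaging targets 0.9 acceptance, a diagonal mass matrix is estimated from
mid-warmup draws, and the leapfrog count is jittered uniformly over the upper
half of a configurable maximum to avoid resonance. Subject effects use a
non-centered parameterization for the choice models (a few dozen decisions
per subject) and a centered one for the descriptive regressions (hundreds of
events per subject, where the data-dominated geometry inverts the funnel).
Defaults are 4 chains x 1000 warmup + 1000 draws; reduced settings (2 chains,
400-600 draws, documented per study) are used for the replicated simulation
studies in the tests and acceptance script. The quadratic family's linear and
quadratic terms are strongly collinear over the uniform TP law, so studies
generating from it use longer trajectories (`max_leapfrog 48`).

Convergence is gated on split-R̂: above 1.05 on any population parameter the
fit is marked failed and summaries refuse to render (warnings are attached
above 1.01 or on divergences). Numerical policy: Bernoulli log-likelihoods use
the `log1pexp` form with no probability clipping; probabilities are never
exactly 0 or 1 for finite parameters.

Posterior summaries report mean, SD and the central 95% credible interval per
population parameter, with an effect labelled credible when the interval
excludes zero. Prediction surfaces over (interrupter TP, interruptee TP)
average the choice probability over the posterior draws of the population
means (a "typical subject" surface; a plug-in method is also available and
recorded). Posterior-predictive calibration tables panel events by quartiles
of interruptee TP and bin them by interrupter TP within panels, comparing
observed rates (with binomial SEs) against the posterior predictive mean and
95% band computed from the fitted subject-level parameters.

## Model comparison

Models are compared by expected log pointwise predictive density estimated
with Pareto-smoothed importance sampling (PSIS-LOO), reported on the LOO-IC
scale (`-2 * elpd`, lower preferred), with event-wise leave-one-out. Events
with Pareto shape k > 0.7 are flagged, k > 1 marked unreliable. Comparisons
are paired over events and refuse to run when data fingerprints differ. A
difference smaller than its paired standard error is reported as
indistinguishable alongside the point verdict. The PSIS computation is
delegated to arviz; degenerate zero-variance likelihood matrices (no
posterior uncertainty) are evaluated directly since the tail fit is undefined
there. The suite cross-checks PSIS-LOO against exact leave-one-out refits on
a small dataset.

A known property of this comparison, visible in the test suite's
model-recovery study: when the generating model is the *monotonic* one, the
quadratic family nests it and hierarchical shrinkage pulls the redundant
quadratic terms toward zero, so the expected LOO penalty for the larger model
is only a few elpd units — the same order as replicate-to-replicate noise.
Point verdicts in that direction are therefore only moderately reliable at
100 subjects x 24 decisions, whereas data generated with a genuinely negative
quadratic term select the non-monotonic family essentially always.

## Descriptive regressions

Separately from the process models, Bayesian logistic regressions relate each
decision to standardized time remaining, participant progress and coworker
progress with all pairwise interactions, and subject random intercepts
(repeated measures; the flag is configurable since the original grouping
structure is not documented). Standardization uses the analysis set after
post-deadline filtering, population-SD convention, with location/scale stored
so the [-2, 2] prediction grids map back to raw units. Coefficient priors are
Normal(0, 2); the intercept SD prior is Half-Normal(1). Prediction heat maps
hold the third predictor at 0 and average probabilities over posterior draws.

## Replicated-study sizes

The test suite and acceptance script run the simulation studies at sizes
chosen to balance statistical resolution against desk-scale runtimes, stated
here as the package's own defaults: parameter recovery uses 20 replicates of
100 subjects x 24 decisions (reduced sampler, 2 chains x 400/400);
model-recovery uses 10 replicates per direction at the same data scale;
regression recovery uses 20 replicates of 3000 events; the PSIS-vs-exact
cross-check uses one 30-event dataset and 30 refits. The acceptance script
runs the same studies at 10/5 replicates.

## Known limitations

- The sampler's diagonal mass matrix cannot rotate away the (tau, omega)
  posterior correlation induced by collinear linear/quadratic design columns;
  mixing for the quadratic family is slower, and bulk-ESS per draw is lower
  than for the monotonic family. Longer trajectories mitigate this.
- Event-wise LOO treats decisions as exchangeable within subjects; leaving
  out whole subjects would answer a different (harder) generalization
  question and is not implemented.
- The simulator abstracts question content, UI rendering and human
  response-time structure; its participant is exactly the fitted model, so
  simulator-sourced datasets cannot expose model misfit.
- Population laws are untruncated Normals; recovery studies use SDs small
  enough that sign-flipped subjects are rare, as documented in each study.
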