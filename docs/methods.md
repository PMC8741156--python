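# Methods

## Decision model

The data level is a two-boundary Wiener diffusion with absorbing boundaries
at 0 and `a`, start point `z = z_rel·a`, drift `v` (sign-coded by stimulus
direction: `+v` for rightward motion, `−v` for leftward; the upper boundary
is the rightward response), within-trial noise `s = 0.1`, and additive
non-decision time `Ter`. Densities use the standard dual-series
representation of the first-passage density: the small-time expansion
(sum over image charges) when it needs fewer terms, the large-time sine
series otherwise, each with an adaptive term count to an absolute series
tolerance of 1e-10. Both boundaries map to one canonical "lower boundary"
form by the reflection `(v, w) → (−v, 1−w)`, and general `s` by rescaling
evidence units by `1/s`. Log densities are computed directly in log space
so that extreme MCMC proposals (large `|v|`, large `a`) cannot overflow;
the defective CDF folds its `exp(−vaw)` prefactor into each term's exponent
for the same reason, and anchors the series to the closed-form absorption
probability `P(upper) = (1 − e^{−2vaz/s²})/(1 − e^{−2va/s²})`.

Non-response trials (no response before the 2.5 s deadline) contribute
`log S(deadline − Ter)` — the survivor function at the decision-time
deadline, consistent with the generator's total-RT deadline. A responded
trial with `RT ≤ Ter` has zero density; its log-likelihood is the finite
penalty −1e10 (configurable) rather than −∞ so Metropolis ratios stay
NaN-free; such proposals are effectively always rejected.

The trial simulator is Euler–Maruyama with a Brownian-bridge crossing
correction per step (crossing probability `exp(−2(a−x₀)(a−x₁)/(s²dt))`),
step 0.5 ms. The bridge term removes the leading-order boundary-crossing
bias; tests hold it to Kolmogorov distance < 0.01 from the analytic
distribution at 1e5 draws. The independent oracle in the tests is a
separately coded plain Euler simulator at dt = 0.1 ms.

## Hierarchy, priors, group difference

Five subject parameters (`a`, `z/a`, `Ter`, `v.diff = v_easy − v_hard`,
`v.mean`), each with hyperparameters (`mu`, `sigma`, `delta`). The group
convention is dyslexia = `mu + delta`, typical = `mu − delta`, so the
difference in group means is `2·delta` but the reported "group difference"
is `delta` itself; negative values mean lower parameter values in the
dyslexia group. Difficulty level 1 is "easy", so `v.diff` is expected
positive. `a` and `Ter` use positive-truncated normal group distributions
and `z/a` a [0,1]-truncated normal, all with normalization constants
included. Hyperpriors are exactly the listing in the README; the second
argument of every normal family is a standard deviation, and Gamma(1,1) is
shape/rate. `delta ~ N(0, 0.01)` is read as SD 0.01 (the alternative
variance reading would widen it to SD 0.1; both are overridable through
`PriorSpec`, and Bayes factors are sensitive to this choice). Catch trials
and responded trials faster than 200 ms are excluded before fitting;
timeouts are retained as censored records.

Age partialling comes in two forms, because "residuals from the line of
best fit" is ambiguous: (default) an in-model covariate, where the group
location for participant p becomes `mu ± delta + beta·(age_p − mean age)`
with `beta ~ N(0, 0.5)` per parameter; and a two-stage route (fit, regress
subject posterior means on age, fit a small normal group-difference model
to the residuals). Both produce a `delta` posterior; neither is asserted to
be the original procedure.

## Sampler

Blocked DE-MCMC. Proposals for a d-dimensional block are
`θ_c + γ(θ_r1 − θ_r2) + ε` with `γ = 2.38/√(2d)`, probability 0.1 of
`γ = 1` (mode jumping), `ε ~ U(−0.001, 0.001)`, Metropolis-accepted.
Chains update one at a time against the current ensemble (sequential
updates preserve detailed balance on the chain product; a fully synchronous
snapshot update would not). Within one chain, all participants' 5-parameter
blocks are proposed and accepted simultaneously: given the hypers their
posterior factors are disjoint, so this is a composition of independent
Metropolis kernels, and it lets the likelihood be evaluated in one batched,
numba-compiled call over all participants and trials. Group-level blocks
(each `mu, sigma, delta` triple; the age-beta block; EEG triples; rho) are
updated per chain afterwards. Per-participant likelihoods and group-prior
terms are cached so group-level updates never touch the data.

Migration: every 14 iterations within the configured window, a random
subset of chains (size uniform on 1..n_chains) proposes a cyclic adoption
of the previous member's state, each accepted by the Metropolis ratio of
full posteriors — never forced. Defaults are 15 chains, 4000 iterations,
1500 burn-in, migration window 500–1100 (behaviour-only model) and 3000
iterations / 1000 burn-in / no migration (joint model). Initialization
draws hypers from their priors and subjects from the implied group
distributions, re-drawn until the posterior is finite (max 100 attempts); a
data-informed jittered start (`init="data"`) is available and used for the
short scaled-down fits, where prior-dispersed starts would spend most of
the budget converging. A NaN from the target aborts the run with the
offending state attached to the raised error.

Convergence is monitored with the classical potential-scale-reduction
statistic (no chain splitting), floored at 1.0 (the `(n−1)/n` factor
otherwise reports values just below 1 for well-mixed chains).

## Inference summaries

Savage-Dickey Bayes factors estimate the posterior density at the null with
a Gaussian KDE (Silverman bandwidth); a normal-approximation estimate is
stored alongside, and a log-BF discrepancy above 0.5 raises a warning.
Kernel estimates degrade when the null lies far (≳3 posterior SDs) in the
tail — exactly when the evidence is already overwhelming — so the
cross-check matters most there. Effect sizes are elementwise `delta/sigma`
posteriors with central 95% intervals. Defective-CDF summaries report RT
quantiles (9 by default) scaled by response probability per group ×
difficulty × correctness plus the miss mass at the deadline; the
model-implied counterpart evaluates the analytic defective CDFs per
participant, averages over the two stimulus directions and the group's
participants, and reads quantiles off the mean curve.

## EEG pipeline

Response-locked epochs (−600..200 ms, 250 Hz) are baselined to the last
100 ms of the random-motion period (resolved per trial from the preceding
stimulus event). Reliable Components Analysis solves the generalized
eigenproblem `R_between w = λ R_within w`, where `R_within` is the
trial-averaged spatial covariance and `R_between` the average cross-trial
covariance (computed via the sum trick `(S Sᵀ − Σ XᵢXᵢᵀ)/(n(n−1))`);
components are ordered by reliability, weights unit-norm, forward
projections `R_within·w` sign-fixed so their largest-magnitude entry is
positive; rank-deficient covariances get diagonal loading with a warning.

The FIR design has one boxcar predictor per (event type, difficulty, lag),
lag window half-open `[−1000, 1000)` ms so 250 Hz yields exactly 500 lags
per condition (a closed interval would give 501). Artifact handling marks
every sliding 2000 ms window (100 ms steps) containing an excursion beyond
±250 µV; all samples in flagged windows are dropped from the regression.
Deconvolution solves `(XᵀX + λI)β = Xᵀy` by Cholesky; `λ = 0` is OLS and
raises a descriptive error on singular systems. The penalty is chosen by
k-fold cross-validation over contiguous time segments (default 5 folds,
grid 0:0.5:30) per participant, sharing one eigendecomposition of each
fold's normal matrix across the grid; the value applied to everyone is the
mode across participants (smallest on ties), so regularisation differences
cannot masquerade as group differences. Slopes are OLS fits to the
response-locked deconvolved waveform over −200..0 ms inclusive, in µV/s;
`EEG.mean` averages the two difficulty levels, `EEG.diff` is easy − hard.

## Joint model

`(v.mean, EEG.mean)` and `(v.diff, EEG.diff)` are bivariate normal at the
population level with correlations `rho_mean`, `rho_diff` (`U(−1,1)`
priors; Savage-Dickey prior density at 0 is exactly 0.5), estimated shared
or per group. EEG measures are fixed observed data (no measurement-error
model); participants without EEG contribute through the exact univariate
marginals. `rho` blocks use reflecting boundaries at ±1. When ages are
supplied, the age covariate acts on the behavioural locations only — the
EEG locations carry no age term, since the slopes enter as data.

## Synthetic-data generator

The generator is the package's stand-in for the study: 2 groups × 2 tasks
× 4 blocks × 38 trials (9 reps × 2 difficulties × 2 directions + 2 catch
trials per block; 152 trials/task), a 2.5 s total-RT deadline producing
non-responses, and RTs from the bridge-corrected Wiener simulator with
subject parameters drawn under the `mu ± delta` convention. Group-level
defaults put the `mu` values at the centres of the hyperpriors (`a` 0.2,
`z` 0.5, `Ter` 0.3 s, `v.mean` 0.3) except `mu_v.diff` = 0.1, chosen so
the two difficulty levels genuinely differ; `sigma` defaults
(0.04/0.05/0.05/0.04/0.06) are typical between-child spreads in the
`s = 0.1` evidence convention, sized so that individual differences are
resolvable from ~150 trials. All `delta` default to 0. Catch trials run at
twice the easy drift and are flagged (and excluded from fitting). A
configurable fraction (default 0) of fast-guess contaminants (uniform RT on
[0, 0.3] s) exercises the 200 ms filter. Jittered period durations are
placeholders, not reconstructions: fixation and random motion U(1.0, 1.5) s,
offset U(0.25, 0.5) s — only event spacing matters for deconvolution.
All randomness flows from one root seed through per-participant
substreams, so tables and EEG are bit-reproducible.

Continuous EEG is the sum of stimulus-locked kernels (fixed biphasic +
sustained shape, amplitude 5/4 µV for easy/hard), response-locked linear
ramps over the 400 ms before each response, and AR(1) noise (coefficient
0.95, stationary SD 10 µV). The ramp slope is `alpha0 + alpha1·v_d +
residual` per difficulty; `EEGLink.for_target_rho` calibrates
`(alpha1, resid_sd)` so that `corr(v.mean, EEG.mean)` equals a requested
value (defaults target 0.44 at the default drift spread). Multichannel
output is topography ⊗ component + channel noise with a smooth default
topography.

What the generator does *not* emulate: real scalp mixtures of many
sources, non-stationary artifacts, ocular components, filter edge effects,
RT-dependent kernel shapes, or any stimulus-level dot kinematics. Passing
tests therefore demonstrate that the estimators recover the structure they
assume, not that real EEG satisfies those assumptions.

## Problem sizes used by tests and the acceptance script

Full study-scale fits (2×50 participants, 4000 iterations) are not needed
to validate the machinery; the shipped checks use: likelihood vs a 1e6
trial Euler oracle; conjugate-hierarchy calibration at 15 chains × 4000
iterations; one recovery fit at 2×12 participants × 152 trials × 15 chains
× 1500 iterations (drift recovery r and R-hat) plus 10 replicates at 800
iterations for the sign of a planted `delta_v.mean = −0.02`; and 10 joint
fits at 2×25 participants × 76 trials × 15 chains × 1000 iterations for
coverage of a planted `rho = 0.44`. These sizes keep the whole validation
run under ~10 minutes on one CPU core.

## Known limitations

- No trial-to-trial variability parameters (sv, st0, sz) — deliberately,
  matching the five-parameter model.
- KDE-based Savage-Dickey ratios are unstable for very large BFs (null far
  in the tail); the stored normal approximation is the better estimate
  there and discrepancies raise a warning.
- The modal-λ constraint is implemented as one global penalty per task; a
  per-group constraint is a config change away but not the default.
- Real-EEG ingestion expects already-cleaned data; acquisition-chain
  preprocessing (filtering, artifact subspace reconstruction, ICA) is out
  of scope.
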