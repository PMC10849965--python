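# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of the package.

## Task model

A session is a sequence of trials.  Each trial: a first-step choice
(left/right; forced-choice on 25% of trials, where only one randomly lit
port is available), a probabilistic transition to a second-step state
(up/down; the common transition, probability 0.8, is fixed per subject as
transition type A — left→up — or B), and a Bernoulli outcome whose
probability depends on the block's hidden state: the good port pays 0.8 and
the other 0.2; in neutral blocks both pay 0.5.

Block reversals are performance-triggered: an exponential moving average of
correct free choices (decay e^(−1/8) per free-choice trial) must exceed
0.75, after which the reversal occurs 5–15 trials later (uniform); neutral
blocks end after 20–30 trials (uniform).  The next hidden state is drawn
uniformly from the other two states (the first block uniformly from the two
non-neutral states); the transition graph beyond "never repeat the same
non-neutral state" is a package choice.

Optogenetic-style stimulation flags can be scheduled on a fraction *f* of
trials under two constraints: the trial after a stimulation is always free
choice, and at least two non-stimulated trials follow each stimulation.
Eligible trials are stimulated with probability f/(1−2f) so the realized
fraction is ≈ f despite the lockout.

A time-step-level view serves the network model: five observable states
(choice, up-active, down-active, reward-at-up, reward-at-down) and five
nose-poke actions; the unrewarded outcome observation is encoded as the
zero vector, so exactly five one-hot codes exist.  Inactive actions leave
the state unchanged; completing a trial takes at least three steps.

## Agent models

All value-like quantities are initialized at the neutral value 0.5; beliefs
at P(up_good) = 0.5.

* **Model-free**: Q_MF(c) ← (1−α)Q_MF(c) + α((1−λ)V(s) + λr);
  V(s) ← (1−α)V(s) + αr.  Asymmetric variant: α⁺ on rewarded, α⁻ on
  unrewarded trials, keyed on the binary outcome; with forgetting, the
  unchosen action and unvisited state decay toward 0.5.
* **Model-based**: V(s) ← (1−α)V(s) + αr and Q_MB(a) = Σ_s P(s|a)V(s) with
  the known 0.8/0.2 transition matrix; forgetting decays the unvisited
  state toward 0.5 (or 0 in the forget-to-zero variant).
* **Inference**: the belief p = P(up_good) is updated by Bayes rule from
  each (second step, outcome) observation.  Standard variant: conditional
  table P(r=1|s,h) ∈ {0.8, 0.2}.  Asymmetric variant: joint table
  P(r,s|h) with rewarded-up 0.4, rewarded-down 0.1 and a *shared* omission
  mass 0.5, making omissions uninformative.  Every trial also applies
  reversal mixing p ← (1−P(rev))p + P(rev)(1−p).  Values are
  V_inf(s) = P(r|s,up_good)p + P(r|s,down_good)(1−p) using the standard
  conditional table for both variants (the alternative — conditionals
  derived from the joint table — is not the default because the asymmetric
  table's role is observation weighting, not payoff estimation), and
  Q_inf(a) = Σ_s P(s|a)V_inf(s).

Net action values are Q_net(a) = Σ_i w_i Q_i(a) + K(a); K adds a bias to
the left action and a perseveration term ±(strength × trace) where the
trace is the previous choice (±1) or, in the multi-trial variant, an EMA of
past choices with rate `persev_alpha` (the single-trial case is the EMA
with rate 1; adding ±p to the two actions is a softmax-equivalent
reparameterization of adding 2p to the previous choice).  Choice
probabilities are a unit-temperature softmax; strategy weights absorb the
inverse temperature.  The per-trial order is: choice probabilities from the
pre-trial state → outcome updates → forgetting → reversal mixing →
perseveration-trace update; forced-choice trials update all latent state
(including the perseveration trace) but contribute no likelihood.

## Fitting

Likelihoods sum log P(observed choice) over free-choice trials; the latent
state is updated on every trial.  Bounded parameters are optimized on an
unconstrained scale (logit / log) with L-BFGS-B at tolerance 1e-6; restarts
draw initial values from Beta(2,2) (unit-range), Gamma(shape 2, scale 0.4)
(positive; the scale reading gives mean 0.8, plausible for softmax weights)
and Normal(0, 5) (unconstrained).  Defaults: 30 restarts for ML, 50 for
MAP.  MAP adds the log prior density in the natural parameter space, so the
MAP point for likelihood-flat parameters is the prior mode.  BIC is
k·ln(n_free_trials) − 2·loglik.  Cross-validation splits by session (10
folds, reduced with a warning when there are fewer sessions).

The likelihood recursions are compiled with numba from the same Python
source as the reference implementation; a test asserts bit-level agreement
with the object-oriented agent API on random sessions.

## Behavioral statistics

Group inference uses per-subject fixed-effects fits followed by one-sample
t-tests on coefficients across subjects — a two-stage approximation to a
mixed-effects model that preserves sign/significance patterns at cohort
scale.  Stay analyses only count opportunities whose *stay* trial is free
choice.  Codings are sum-to-zero with left/rewarded/common as the positive
level; the 3-level correctness factor uses the orthogonal pair
{correct−incorrect, (correct+incorrect)/2 − neutral}.  Logistic fits fall
back to an L2-penalized fit when separation is detected.  Stimulation
analyses drop stay opportunities whose predictor trial sat inside the
2-trial post-stimulation lockout (it could never have been stimulated).
The Bayes factor for a coefficient against a point null integrates a
Normal(mean, sd) data likelihood over a uniform H1 on [0, bound] (either
sign), evaluated with normal-CDF closed forms in log space.

The lagged cue-response regression includes, as printed, the lag-1
same/different-second-step codes *and* the unlagged previous-reward code,
which are exactly collinear (same + different = previous reward); OLS via
pseudo-inverse yields minimum-norm coefficients, and the identified
quantity is the same-minus-different contrast, which the tests use.

## Photometry

The generator emulates a dopamine recording: alpha-function transients
(τ = 0.2 s) at choice (+Q_inf(c) ± movement laterality), second-step cue
(+V_inf(s) − Q_inf(c)) and outcome (+r − V_inf(s)); a tonic reward-rate
component (EMA, τ = 10 trials; the behavioral regressor variant uses τ = 8);
double-exponential bleaching (τ 60 s and 2000 s); a 0.3–3 Hz band-limited
motion artifact shared with the control channel; and white noise.  Event
timing: 200 ms fixed delays, 1 s second-step cue, gamma-distributed
behavior-determined intervals, 2–4 s inter-trial intervals.  It does *not*
emulate: sensor kinetics differences (GCaMP vs dLight), rotary-joint step
artifacts, hemisphere bookkeeping across fibers, or non-stationary
amplitudes — so passing recovery tests demonstrate pipeline correctness,
not robustness to every real-data pathology.

Preprocessing: median filter (5 samples) → 5 Hz low-pass → motion estimate
as the least-squares projection of the 0.001–5 Hz band-passed signal onto
the band-passed control, subtracted → double-exponential detrend
(single-exponential fallback on fit failure) → per-session z-score.

Warping: the two behavior-determined intervals (initiation→choice and
second-step cue→poke) are linearly resampled to fixed target lengths
(defaults 0.6 s and 1.3 s; per-session medians when targets are not
supplied — shared targets are required to stack subjects); all other
segments are copied sample-exact.  The analysis grid subsamples warped
columns with stride 6 (≈ 21.7 samples/s at 130 Hz).

Per-timepoint Lasso: predictors standardized to mean 0, variance 1; the
outcome (already z-scored per session) is not standardized; penalty chosen
per regression by 5-fold cross-validation over a log-spaced grid
1e-4…1e1.  Group statistics: one-sample t across subjects per timepoint,
Benjamini–Hochberg over timepoints within predictor, Cohen's d =
mean/SD (zero-variance cells are capped and flagged).

## Network model

PFC: one layer of 16 gated recurrent units,
h′ = (1−z)∘h + z∘tanh(W_x x + W_h(r∘h) + b); linear head predicting the
next input's 5-dim observation code.  Base variant input: one-hot
observation ⊕ one-hot previous action (10-dim); gated variant: the
observation gated by reward (5-dim; zero vector on unrewarded steps, which
coincides with the zero encoding of the no-reward observation).  BG: input
= observation ⊕ PFC activity (21-dim) → 10 shared ReLU units → scalar value
and 5-way softmax policy.

Training: episodes end after 100 trials or 600 steps; weights update
between episodes.  PFC minimizes the next-input MSE with full-episode
backpropagation through time (Adam, lr 0.01).  BG uses advantage
actor-critic on full-episode discounted returns (γ = 0.9): summed critic
squared error, policy-gradient term with the advantage treated as constant,
entropy bonus 0.05 (Adam, lr 0.05 — an adaptive optimizer is required for
stability with summed episode losses; plain SGD diverges at this rate).
Initializers follow standard deep-learning-framework defaults: Glorot
uniform input kernels, orthogonal recurrent kernels per gate, zero biases
except a 0.1 bias on the BG ReLU layer (avoids dead units).  Both backward
passes are checked against central finite differences at 1e-4 relative
tolerance.

The network's task uses the binary hidden state (no neutral blocks) and
free-choice trials only.  A battery is 12 runs, 500 episodes, consecutive
seeds; after training, 10 further episodes are rolled with frozen weights
and analyzed.  Runs are included if their frozen-policy reward per trial
exceeds 0.55 (chance 0.5 under random choice, +0.05 margin); with a
near-ceiling of ≈ 0.60 (reversals cap attainable performance), typically
9–11 of 12 runs pass.

Counterfactual valuation: at each trial's second-step entry the reached
state's value is read from the BG; the other state's value re-runs the PFC
step from the same prior hidden state with the substituted observation
(identical inputs in the gated variant, where only the BG's observation
input differs).  The per-run effect of reward on a state's value is the
mean next-trial-minus-current value change after rewards minus after
omissions, for the same and the different state; cross-run t-tests
summarize.

Simulated stimulation: on 25% of trials the single-step actor-critic
update induced by a prediction error of +1 (both heads; the shared layer
couples them) scaled by the BG learning rate is applied counterfactually —
apply, evaluate the next trial's stay probability from the logged PFC
state, revert.  Stay probability is regressed on transition, outcome and
stimulation codes (±0.5); cross-run t-tests summarize.  Choice-time
stimulation raises the stay probability; outcome-time stimulation does not,
because the update strengthens poke-up/down in the second-step state, which
does not bear on the next choice-state decision.

## Experiment problem sizes

The packaged experiments (`twostep.experiments`) use: 12 network runs × 500
episodes (+10 frozen evaluation episodes); parameter recovery with 18
subjects × 29 sessions × 350 trials (the cohort scale of the modelled
dataset) at 10 optimizer restarts; the stay-pattern experiment with 12
subjects × 10,150 trials; photometry with 6 subjects × 400 trials at the
stride-6 grid.  Fitted-scale parameter draws: w ~ U(3,7), α⁺ ~ U(0.4,0.8),
α⁻ ~ U(0.1,0.5), forgetting ~ U(0.05,0.3), P(rev) ~ U(0.05,0.2),
bias ~ N(0,0.2), perseveration ~ U(0,0.5).

## Known limitations

* The stay gap after omissions is small but genuinely nonzero for the
  asymmetric-inference agent (≈ −0.07 at the above scales): conditioning on
  an omission at second step *s* carries 4:1 likelihood odds that *s* is
  not the good port, which correlates with the belief through past rewards.
  It is an order of magnitude smaller than the reward-trial gap (≈ 0.33),
  which is the qualitative asymmetry of interest.
* Group-level inference is two-stage (per-subject fits + t-tests), not a
  full random-effects GLMM; a GLMM backend can be attached where exact
  variance partitioning matters.
* BIC separates the asymmetric model-based and asymmetric inference
  strategies only weakly (per-trial gap < 0.01 nats at 10k trials/subject),
  while both separate clearly from model-free — the two strategies make
  near-identical trial-level predictions on this task.
* The network model is a minimal circuit abstraction: no anatomical unit
  mapping, no within-trial dopamine dynamics, single fixed architecture.
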