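# Methods

## Model

The agent is a continuous-time rate network of N neurons (default 256 at
full scale; desk-scale experiments in this repository use 64), 80%
excitatory and 20% inhibitory. Firing rates r(t) evolve as

    tau dr/dt = -r + W_rec r + W_in u + b + sqrt(2 tau) sigma_rec xi(t),

integrated by the Euler method with dt = 20 ms (alpha = dt/tau = 0.2) and
rectified to non-negative rates. tau = 100 ms, sigma_rec = 0.15. Inputs u
are 16 scalar channels (fixation cue; five one-hot task rule cues; one
quantity and one probability channel per good A-E), normalized to [0, 1],
with baseline 0.2 and input noise sigma_in = 0.01.

Dale's law is enforced by a magnitude reparameterization: the stored free
weights are unsigned and the effective recurrent weight is |w| times the
presynaptic sign; input and readout matrices are constrained non-negative
the same way. This keeps gradients informative compared with clipping
sign violations after each update; the two schemes agree on the constraint
set. Two linear readouts share the population: a softmax policy over four
actions (fixate, choose slot 1-3) and a scalar value estimate.

Initialization: recurrent magnitudes are Gamma(shape 4, scale 4) rescaled
to spectral radius 1.5 before the sign mask; W_in ~ U(0, 1/16); readouts
~ U(0, 0.4/N); biases zero.

### Noise discretization

The continuous noise term sqrt(2 tau) sigma xi(t) is realized per Euler
step as an i.i.d. Gaussian of standard deviation sigma * sqrt(2/alpha)
added inside the bracket (so the effective per-step increment has standard
deviation sigma * sqrt(2 alpha)). A linearized unit then has stationary
variance 2 sigma^2 / (2 - alpha), which the test suite verifies against
simulation. Input noise uses the same convention on the observation
channels.

## Tasks

Five trial-based economic choice tasks share one structure: fixation
(uniform 500-1500 ms), rule cue (uniform 500-1500 ms), offer presentation
(uniform 500-1500 ms; duration not otherwise constrained, so it uses the
same range, config-exposed), and a response window of up to 1000 ms in
which the fixation cue turns off. Offers are (good, quantity, probability)
triples with value rho * q * p; q ~ U(0, 10/rho) so all goods span the
value range [0, 10]; p ~ U(0, 1) (exactly 1 in the deterministic standard
task); offers with value < 1 are redrawn. Intrinsic values default to
rho = {A: 3, B: 2.5, C: 2, D: 1.5, E: 1}: rho_A = 3 and rho_E = 1 anchor a
strictly decreasing ranking, rho_C = 2 follows from the generalization
protocol's half-maximum-quantity condition (q_C = 2.5 of a 0-5 range), and
B and D sit at the midpoints. Choosing before the response
window aborts the trial with reward -1. Choosing slot X delivers
rho_X * q_X with probability p_X, else 0 (independently per good for
bundles). Failing to respond within the window also aborts with reward -1:
treating the timeout as neutral makes indefinite fixation a reward-neutral
absorbing policy, and every training run converged into it; penalizing the
timeout like a fixation break removes that attractor. Rule cues stay on
from the rule epoch to the end of the trial; in the sequential task each
offer is visible only during its own epoch, so the decision requires
working memory. Choice slots are bound to goods (slot 1 = C, slot 2 = E)
regardless of presentation order; the order (C first or second) is
randomized and recorded.

For neural analyses, trials use fixed 1000 ms epochs so time bins align
across trials; sequential activity aligns to second-stimulus onset by
construction.

The generalization protocol trains on a constrained "cross" of offers:
with probability 1/2 both probabilities are fixed at 0.5 and quantities
span their ranges, otherwise quantities are fixed at half maximum
(q_C = 2.5, q_E = 5) and probabilities span [0, 1].

## Training

Proximal policy optimization with the clipped surrogate
min(rho_t A_t, clip(rho_t, 1 - eps, 1 + eps) A_t), value loss, and entropy
bonus; gamma = 0.99, eps = 0.1, c1 = 0.5, c2 = 0.01, Adam at 2.5e-4 with
global gradient norm clipped at 1.0; 20 parallel environments, 128 steps
per rollout, 4 optimization epochs of 4 minibatches of whole sequences
with backpropagation through time from the stored rollout-initial hidden
state. Advantages are the plain bootstrapped-return residuals
A_t = R_t - V(s_t) (no temporal-difference mixing); returns truncate at
trial boundaries. The hidden state resets to zero at each trial end and is
carried across rollout chunks within a trial. Rollout noise realizations
are stored and replayed exactly during the optimization epochs, so the
importance ratios are exactly 1 before the first update (verified in the
test suite, along with the full analytic-versus-finite-difference gradient
check of the backpropagation).

Training this architecture with softmax action selection on trial
structures that demand ~100 consecutive fixation steps has two failure
modes that the stock algorithm does not handle: (1) during improvement
phases the lagging critic makes advantages uniformly positive, which
inflates the logit of the batch-dominant action (fixate) without bound
until the policy saturates; (2) once the softmax saturates, the entropy
gradient and the PPO ratio gradient both vanish identically, so nothing in
policy space can recover exploration. Four numerical safeguards address
this, all config-exposed, none altering the stated objective
coefficients:

- advantages are batch-centered (removes the common-mode inflation) and
  divided by max(1, std) — scaled down but never amplified, since
  unit-normalizing a reward-sparse batch amplifies noise until it drowns
  the entropy bonus;
- the value error enters through a Huber loss (delta = 1), bounding critic
  gradients through the shared recurrent trunk (rewards reach 10);
- decoupled weight decay on the actor head provides a parameter-space
  recovery force that still operates at saturation. A strong decay (0.3)
  caps the fixation logit gap and with it completion at ~95%, so the decay
  is relaxed to 0.02 while the behavior policy's recent completion rate
  exceeds 90% and restored when it degrades — a rescue brake rather than a
  permanent regularizer;
- per-rollout optimization epochs stop early when the approximate KL
  exceeds 0.02.

Performance criteria: >= 99% of held-out trials completed without breaking
fixation, and >= 90% of completed trials choosing the highest-value slot,
measured on a seeded test set with actions sampled from the policy.
Learning passes through the expected phases: fixation holding, random
responding, then value-based choice.

## Behavioral model

Choices are fit by maximum likelihood to logistic (binary tasks) or
softmax (ternary) models over powered offer values
V_X = rho_hat_X * q_X * p_X^gamma_hat, with consistency eta_hat as the
inverse temperature on log value ratios, an additive order-bias term
eta * eps' * Order in the sequential task, and rho_hat_E = 1 as the
reference. gamma_hat is fit only for probabilistic tasks (fixed to 1 for
the standard task). Positive parameters are log-transformed;
Nelder-Mead from five starts; eta is capped at 1e3 and flagged when data
are separable. Standard errors come from the finite-difference observed
information matrix at the optimum.

## Analyses

- Single-neuron selectivity: per neuron and 20 ms bin, ordinary
  least-squares regression on each decision variable (OVC, OVE, CV, CH,
  value sum, value difference, conjunctive CVC/CVE); a neuron-time point
  is selective when p < 0.05 and R^2 >= 0.005, labeled by the variable
  with maximum R^2 among those passing. No multiple-testing correction
  (two-step criterion as stated); with 8 candidate variables the
  family-wise false-positive rate on untuned neurons is accordingly
  ~1 - 0.95^8, which the fixture tests calibrate empirically rather than
  assuming 5%.
- Temporal stability index: fraction of a neuron's selective bins carrying
  its modal label; ties break to the first variable in the canonical order
  (OVC, OVE, CV, CH, sum, diff, CVC, CVE).
- Delta-R^2 coding analysis with a strict (max R^2 >= 0.5) or lenient
  (two-step criterion on either variable) inclusion rule.
- Participation ratio (sum lambda)^2 / sum lambda^2 of the covariance of
  activity from the last 200 ms of the offer period, concatenated across
  trials; PCA uses per-neuron mean centering, no variance scaling.
- Principal angles between task subspaces spanned by the top round(PR)
  PCs of rule-period activity; the largest canonical angle is reported
  (config switch for the mean).
- Orthogonal Procrustes alignment of mean task representations across
  networks (closed-form SVD solution).
- Task-variance clustering: per-neuron variance per task, max-normalized,
  k-means on E and I populations separately with k in [2, 20] chosen by
  silhouette (20 restarts, fixed seed).
- Reaction times from response-phase onset to choice execution, regressed
  on |value difference|.
- Connectivity: Pearson structure of input-weight columns; selectivity
  index (w_qC - w_qE)/(w_qC + w_qE); reduced pool-by-pool mean connectivity
  over functional labels assigned at the time of peak population
  selectivity in the offer period (choice pools split by CH slope sign);
  the competitive-recurrent-inhibition score is the mean cross-choice
  minus same-choice I-to-E weight magnitude; SVD spectrum of W_rec with a
  participation-ratio effective rank.
- Lesions: recurrent removal (W_rec = 0) and clamping listed neurons to
  zero rate throughout the trial, evaluated against the intact network on
  identically seeded trial streams.

## Toy feedforward model

Units r_i = [alpha_i (q + p) - beta_i E[qp]]_+ tile the offer plane;
E[qp] is estimated by Monte Carlo under the task's value >= 1 truncation.
The sweep over shared (alpha, beta) locates the regime where the top
principal component of the population is better explained by the product
q*p than by the sum q+p. Because the construction ties the quantity and
probability weights (w_q = w_p), every unit — and hence every linear
functional of the population — is a function of s = q + p alone; maximizing
corr^2(f(s), qp) - corr^2(f(s), q+p) over all functions f of s bounds the
achievable advantage at ~0.28 on the uniform offer grid, and the ReLU
family realizes at most ~0.23. The multiplicative regime therefore exists
and is substantial, but advantages above ~0.28 are impossible under this
construction. The segregated variant (independent populations per offer)
yields principal axes aligned with the individual offer values; adding a
mixed population receiving summed inputs rotates the axes to value sum and
difference.

## Synthetic rate fixture

The planted-tuning generator emulates fixed-epoch trials whose offer-period
rates are baseline + slope * variable + Gaussian noise for specified neuron
groups (optionally gated by a conjunctive condition), with realistic offer
value distributions. It reproduces the epoch structure and trial variables
of the real task but not recurrent temporal dynamics, noise correlations,
or E/I structure — fixture-based tests validate the analysis estimators
(label recovery, TSI, PR, clustering), not claims about trained networks.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
networks of 64 neurons (48 excitatory); standard-task training budget
2.2-2.4e7 environment steps with early stopping once the criteria hold
with margin; ternary 3.5e6; value-weight cohort of five risky networks
(rho_C in {1..5}, 2e6 steps each, stopping early at the first healthy
evaluation — completion >= 0.85 at above-chance accuracy); constrained-
offer generalization network 3.5e6 steps. Evaluation sets of 2000-2500
trials (full-scale protocol: 25,000).
Cohort-level replications at these budgets retain the qualitative
orderings but reach lower accuracy than the full-scale criteria,
particularly on the risky task, whose multiplicative integration develops
slowly.

## Known limitations

- The risky, bundles, ternary and sequential tasks need substantially more
  training than the standard task; at desk scale their accuracy typically
  plateaus in the 0.6-0.8 range, so analyses conditioned on
  trained-to-criterion networks of those tasks are run on the best
  available networks instead.
- Stochastic trial counts: learning times vary several-fold across seeds;
  oscillations (brief completion collapses with recovery through the decay
  brake) are visible in training logs and are expected.
- The behavioral fitter treats each task independently; no hierarchical
  pooling across networks.
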