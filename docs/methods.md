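# Methods

## The selection model

A trial presents N items `z_j = (x_j, y_j, c_j)` with coordinates in display
units (y increasing upward) and a two-level class label `c_j ∈ {A, B}`.
Selections are modelled as sampling without replacement. Given the sequence
selected so far, the unnormalised weight of a remaining candidate j is

    w(j|i) = p_a(c_j) · p_s(c_j|c_i) · exp(−ρ_δ δ_j + ρ_ψ ψ_j) · g(φ_j)

with

* `p_a(A) = invlogit(b_a)`, `p_a(B) = 1 − invlogit(b_a)` — class preference;
* `p_s = invlogit(b_s)` if the candidate's class matches the last selected
  item's class, else its complement — stick/switch bias;
* `δ_j` — Euclidean distance from the current item divided by δ0
  (default 20 display units), so that ρ_δ lives on the same numeric scale
  as the other parameters;
* `ψ_j = 1 − Δ/π`, where Δ ∈ [0, π] is the shortest angular difference
  between the previous movement heading and the bearing of the candidate;
  ψ = 1 straight ahead, 0.5 perpendicular, 0 reversal;
* `g(φ) = exp(Σ_k θ_k · vM(φ; μ_k, κ))` — a log-linear gain over the
  candidate's absolute bearing, with von Mises component densities
  (Bessel-normalised, so κ changes shape not scale) centred on the K = 4
  cardinal directions (K = 8 adds the obliques) and a shared fixed
  concentration κ (default 20, configurable; a sensitivity sweep over
  κ ∈ {10, 25, 50} is a one-line config change).

Selection probabilities are the weights normalised over the remaining set;
previously selected items have probability exactly zero.

Two boundary rules are built in and unit-tested: the first selection of a
trial uses the class weights only (no spatial reference point exists), and
the second omits the ψ term (no previous movement vector).

Conventions chosen where equivalent formulations exist (both are
probability-identical up to constants that cancel in the normalisation, but
they change the sign/scale of the raw parameters, so posteriors should not
be compared numerically across implementations without converting):

* ψ is the inverted, normalised alignment (1 = ahead) with a positive
  exponent, so ρ_ψ > 0 means forward momentum; the raw angular difference
  with a negative exponent is the same model with ρ_ψ scaled by π.
* The directional gain is `exp(θ·vM)` so θ_k > 0 attracts selections toward
  direction μ_k.
* The class weight applies to the candidate item, the stick weight to the
  (candidate, previous) pair.

Model versions: v1.0 (ψ, no absolute direction), v1.2 (no ψ), v1.3 (ψ + 4
directions), v1.4 (ψ + 8), v1.5 (4 directions, no ψ). The version that
computes distances differently in the original family (v1.1) is not
implemented because its definition is not publicly specified; requesting it
raises an explicit unsupported-version error.

## Hierarchical structure and priors

Each of b_a, b_s, ρ_δ, ρ_ψ and each θ_k has a fixed effect per condition
and an observer-level random effect per condition. The eight core random
effects (2 conditions × 4 parameters) share a full covariance matrix;
direction-weight random effects are modelled independently (a full 16×16
covariance is poorly identified at typical study sizes). Priors:
b_a, b_s ~ N(0, 1.5); ρ_δ ~ N(1, 0.25); ρ_ψ ~ N(0, 1); θ fixed effects
~ N(0, 1) (configurable); group SDs ~ Exponential(5); correlation matrix
~ LKJ(η = 2) (η configurable; neither the θ prior nor η has a canonical
published value, so both are explicit `FitConfig` fields).

## Fitting

The softmax structure makes every selection a conditional-logit observation:
the class and stick normalising constants cancel, leaving a linear predictor
`η_j = b_a·[c_j=A] + b_s·[match] − ρ_δ δ_j + ρ_ψ ψ_j + Σ θ_k vM_k(φ_j)`.
Per observer × condition the log-likelihood is therefore concave with
analytic gradient and Hessian.

The hierarchical fit runs in two stages.

1. **Per-observer estimates.** Each observer × condition block is fitted by
   Jeffreys-penalised (Firth) conditional-logit regression — the penalty
   `+½ log det I(β)` removes the O(1/n) away-from-zero bias of maximum
   likelihood, which otherwise propagates into the group means — plus a very
   small ridge (10⁻²) that keeps rare separable cases finite. The inverse
   observed information V_i summarises the evidence as
   `β̂_i ~ N(β_i, V_i)`. The curvatures are then pooled across observers
   (rescaled by each observer's number of selection events): shrinkage
   weights should reflect how much data an observer contributed, not where
   their parameters sit — an observer with a strong stick or proximity bias
   produces a flatter likelihood and would otherwise be systematically
   down-weighted, biasing the group mean toward weak-bias observers. Both
   behaviours are `FitConfig` switches.

2. **Hyperparameters.** The stage-one summaries imply the exact marginal
   `β̂_i ~ N(μ, Σ + V_i)`. Because μ is conjugate given the variance
   parameters, it is integrated out analytically (the marginal over the
   variance parameters is then the Bayesian analogue of REML, avoiding the
   classic downward bias of joint-mode variance estimates). The remaining
   ~44-dimensional posterior over (log SDs, unconstrained correlation
   Cholesky) is either maximised with a Laplace approximation
   (`backend="map"`, seconds) or sampled with an affine-invariant ensemble
   sampler run as four independent chains whose R-hat must fall below 1.01
   (`backend="mcmc"`; non-convergence is flagged in the diagnostics and
   warned about, never silently accepted). Fixed-effect draws are then
   exact conjugate Gaussian draws given each variance draw. Per-observer
   parameters come from the same conditional-Gaussian algebra (shrunken
   point estimates, or draws for posterior-predictive work).

An empty training table switches the fit to prior-predictive mode: draws
come directly from the priors (LKJ samples via the vine method), which the
test suite uses to confirm prior recovery.

Train/test protocol: the first ⌈T/2⌉ trials per observer × condition (by
trial index) form the training set, the remainder the test set; an observer
with a single trial goes to train with a warning. Inexhaustive trials
contribute likelihood only for their observed selections (truncation — no
stopping model).

## Synthetic data

`simulate_dataset` emulates typical screen-based two-class foraging studies:
N_items targets at the centres of an n_cols × n_rows grid spanning a
1280 × 720-unit display, displaced by isotropic Gaussian jitter (SD 10
units), half of each class, collected exhaustively. Defaults (40 items, 8×5
grid, 10 trials, 2 conditions) match the common designs in this literature
(16–58 observers, 10–20 trials, 20–40 targets). The display size and jitter
magnitude are declared defaults, not estimates of any particular published
stimulus set. One seed drives population sampling, stimulus generation and
trial simulation through a single generator, so a dataset is reproducible
from its seed alone.

What the generator deliberately omits — and hence what passing tests do not
establish about real data: initial-selection spatial biases (real observers
start top-left or centrally; simulated first selections use class weights
only, matching the model's own assumption), distractors, stopping rules for
inexhaustive designs, target motion, and any 3D geometry.

The default recovery study (also behind `fomo recover`) generates 30
observers × 2 conditions × 10 trials × 40 items from b_a = 0.5, b_s = 1.5,
ρ_δ = 1, ρ_ψ = 0.5, horizontal θ = (1, 0, 1, 0) and observer SDs of 0.3 on
every parameter, then checks each group-level fixed effect against its 95%
highest-density interval over 20 replicates. Because sixteen interval checks
per replicate are correlated and a perfectly calibrated fit still misses
each ~5% of the time, the pass criterion is the aggregate coverage across
effects × replicates (≥ 0.90), not a per-effect threshold — a per-effect
bound at the same level would fail a substantial fraction of runs under
perfect calibration.

## Path statistics

* **Runs / maximum run length** — maximal blocks of one class in the
  selection sequence.
* **PAO** — `100·(L_actual − L_opt)/L_opt`, with L_opt the shortest *open*
  Hamiltonian path (free endpoints, not a cycle) through the selected
  points: exact subset dynamic programming up to 15 points, nearest
  neighbour + 2-opt above. The heuristic is an upper bound on the true
  optimum; the observed path is admitted as a candidate, so PAO ≥ 0 always,
  but heuristic-regime PAO can slightly understate the excess.
* **best-r** — the larger of |corr(rank, x)| and |corr(rank, y)| with
  Pearson correlation and selection rank 1..n; undefined (NaN) when both
  coordinates are constant.
* **Intersection rate** — crossings between non-consecutive path segments;
  proper crossings count once, endpoint touching does not count, collinear
  overlap counts as one. Verified against an orientation-test oracle.
* **Lévy exponent μ** — continuous power-law tail fit to the
  inter-selection distances: x_min by Kolmogorov–Smirnov minimisation over
  up to 100 candidate values (keeping at least 10 tail points), μ by the
  continuous MLE above x_min. Distances are used untruncated. Fits with
  fewer than 50 distances are flagged `low_n`; per-trial sequences (≤ ~40
  distances) are therefore pooled per observer × condition in the tidy
  statistics table. All-equal distances return a degenerate flag instead of
  a number.
* **Prediction accuracy** — fraction of selections (positions ≥ 2) whose
  item-wise model prediction matches the observed item, aggregated overall,
  per observer (with an HPDI over posterior draws) and per position. The
  chance baseline averages `1/(items remaining)` over all N selection
  positions, `H(N)/N` — 0.11 at N = 40, 0.18 at N = 20. This convention
  (first selection included) is the one that reproduces those printed
  two-decimal values; scoring after the first selection changes the N = 20
  baseline at the second decimal.
* **Stick/switch confusion** — predictions labelled stick/switch against
  the previous observed item's class; reported as P(predicted stick |
  observed stick) and P(predicted switch | observed switch) per condition.
* **Scaled error summary** — for observed-vs-predicted comparisons, the
  mean absolute difference per statistic divided by the between-observer SD
  of the observed statistic (making statistics comparable); zero observed
  spread yields an undefined flag.

## Numerical choices and degenerate inputs

* All weight computations run in log space; von Mises densities use the
  exponentially scaled Bessel function, so large κ cannot overflow.
* Probability normalisation is exact to 1e−12 and property-tested, as are
  version nesting (v1.3 at θ = 0 equals v1.0) and the ψ-convention and
  rotation equivalences.
* Coincident points make angles undefined and raise, rather than return, a
  value; all-zero candidate weights raise a degenerate-weights error.
* Ties in weights are never broken deterministically: prediction is always
  by sampling or by reporting the full distribution.
* HPDI is the narrowest sorted window containing ⌈mass·n⌉ draws.
* CSVs are written at 17 significant digits and read back with round-trip
  float parsing, so result tables survive a write/read cycle bit-for-bit.

## Known limitations

* The two-stage fit is an approximation to full joint MCMC over the exact
  likelihood; with very few selections per observer (tens rather than
  hundreds) the Gaussian stage-one summary becomes crude and group-level
  proximity/stick estimates can shrink noticeably — the recovery suite
  covers the 40-item, 10-trial regime, not sparser designs.
* No stopping model: inexhaustive foraging is handled by truncation only.
* Initial-selection biases are neither modelled nor simulated.
* The heuristic PAO regime (> 15 points) is approximate by construction.
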