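# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic benchmark can and cannot show.  Notation: inputs are the seven
measured process channels `u1..u7` (culture volume L, agitator power W, pH,
substrate feed temperature K, fermenter temperature K, substrate feed rate
g/h, aeration rate L/h); the quality variable `y` is penicillin
concentration (g/L).

## Data handling

Inputs are z-scored with the column statistics (mean, sd with ddof = 1) of
the *whole* training block, labeled and unlabeled together.  The inputs of
unlabeled samples are observed, so pooling is legitimate, and it keeps the
Ward tree and the mixture model on one fixed scale across learning
iterations.  The target is z-scored per model fit with the current labeled
set's statistics and predictions are back-transformed; constant targets fall
back to unit scale.  Constant input columns are rejected at standardizer-fit
time rather than silently producing NaNs.

The initial labeled subset (default 8 of 400, i.e. 2%) is drawn uniformly at
random under a recorded seed; a time-stratified option exists for
reproducibility studies.  Sample identity is a stable integer from file row
order; every cross-module reference uses ids, never row positions.

## Gaussian process regression

Zero-mean GP with the isotropic squared-exponential kernel
`σ_f² exp(−‖x_i−x_j‖²/(2l²)) + δ_ij σ_n²`.  An automatic-relevance
(per-dimension) length-scale variant is deliberately out of scope — local
models see as few as a handful of points early in the loop, where 9 extra
hyperparameters would be unidentifiable.

* **Fitting.** The log marginal likelihood is maximized with L-BFGS-B on
  `(log l, log σ_f², log σ_n²)`; the surface is multimodal, so 5 restarts are
  drawn log-uniformly from `[1e-2, 1e2]³` (seeded) in addition to a
  moment-based start `(1, var(y), var(y)/10)`.  Gradients are analytic
  (`∂L/∂θ = ½ tr((ααᵀ − K⁻¹) ∂K/∂θ)`, `α = K⁻¹y`).  Box bounds `[1e-6, 1e4]`
  on every parameter keep the kernel matrix invertible even for duplicated
  inputs (σ_n² cannot collapse to exactly zero during optimization).
* **Numerics.** All solves go through a Cholesky factorization with a jitter
  ladder `0, 1e-10 … 1e-6` (relative to the mean diagonal) on failure.
  Posterior variances are clamped at zero; they can go negative by ~1e-12
  through round-off, never more (checked against dense linear algebra at
  1e-8).
* **Prediction.** The posterior mean is the point estimate.  The prior
  self-covariance at a query includes σ_n² by default (predicting the noisy
  observation); `include_noise=False` gives the latent-function variance.

## Gaussian mixture phase model

EM on the labeled *inputs* only — the fusion weights at query time depend on
x alone, so training the mixture on x keeps train/test treatment consistent.
Responsibilities are computed in log space (`logsumexp`), so far-away points
cannot underflow to 0/0.

* **Initialization**: k-means++-style seeding of means from data rows,
  covariances initialized to the pooled covariance, weights uniform; best
  log-likelihood of 8 seeded restarts (16 inside order selection, where a
  single bad local optimum would corrupt the whole BIC curve).
* **Regularization**: every M-step adds `1e-6 · tr(Σ_pooled)/m` to each
  covariance diagonal.  The floor is keyed to the *pooled* data covariance,
  not the component's own, so a component cannot buy unbounded likelihood by
  collapsing onto near-duplicate samples.
* **Convergence**: log-likelihood gain `< 1e-6` or 500 iterations.  The
  ascent property (non-decreasing within 1e-9) is asserted in tests on every
  run.

### Number of phases

The order-selection criterion is `BIC(K) = −2 log L + 3K log N`, with the
penalty in exactly this `3K log N` form (a standard free-parameter-count
penalty, `(K−1) + Km + Km(m+1)/2` per component set, is available behind
`penalty="free-params"` but is not the default).  Two facts shape the
selector:

1. For 7-dimensional inputs the `3K log N` penalty is far below the
   free-parameter count (36 per extra component), so even structureless data
   gains raw BIC from extra components.
2. On trajectory-structured process data the BIC decreases essentially
   *monotonically* in K: additional components keep paying for fine
   trajectory detail, and the literal minimizer lands at the top of
   whatever range is scanned.

`select_k` therefore reads the curve the way a practitioner reads the elbow
plot: the selected K is the smallest one after which the next component's
BIC improvement falls below 15% of the total BIC decline over the scanned
range.  Gains below a significance floor of `max(4·p_extra, 6·log N)` —
the overfitting scale of one spurious component, inflated for the upward
bias of best-of-restarts maximization — are treated as noise, which makes
the selector return K = 1 on single-cluster data.  `method="argmin"` gives
the literal minimizer (ties toward smaller K) for comparison.

Components that end up with fewer than 3 hard-assigned labeled samples are
merged into the component whose mean is nearest in Mahalanobis distance
(under the receiving covariance) before local models are fitted: a GP on
fewer than 3 points is ill-posed.

## Ward tree and pruning

The pool tree is built once per experiment on standardized inputs, by greedy
agglomeration of the pair with the minimal error-sum-of-squares increase,

    Δ(c1, c2) = ESS(c1 ∪ c2) − ESS(c1) − ESS(c2)
              = n1 n2/(n1+n2) · ‖o1 − o2‖²,

maintained incrementally in the Lance–Williams centroid form (validated in
tests against direct recomputation of the merged-cluster ESS).  Ties break
toward the lexicographically smallest pair of minimum member ids, and merged
centroids are accumulated smaller-min-id first, so the tree is invariant to
row permutation bit for bit.  Ward reducibility makes merge heights
non-decreasing; the initial working pruning (default 150 nodes for a
392-leaf pool) is the forest left by undoing the final `max_nodes − 1`
merges.

## Active sampler

Classes adapt the classification-style machinery to regression: the labeled
target is quantile-binned into 3 levels (mirroring the three physiological
phases), with bin edges frozen from the initial labeled set so node
statistics stay comparable across iterations.  A GMM-component labeling
scheme is provided as an alternative.  Per node, statistics use *queried*
samples only; the confidence half-width is

    Δ_{v,c} = d/n_v + sqrt(d · p(1−p) / n_v),   d = 1 − n_{v,c}/n_v,

class c is admissible when `(1 − p^LB_c) < β (1 − p^UB_{c'})` for every
rival c′ (β = 2), the node's error is `1 − p` of its most probable
admissible class (1 if none), and unqueried nodes carry vacuous `[0, 1]`
bounds.  Note a consequence of the printed half-width: a node whose queried
samples are all one class has `d = 0` and collapses its bounds to `[1, 1]`
— one label "solves" a node until contradicted.

* **Refinement** minimizes the *leaf-mass-weighted* total error
  `Σ w_v ε̃_v`, `w_v` = subtree leaf count / pool size: comparing a parent's
  raw error fraction against the sum of two children's fractions would be
  dimensionally inconsistent (a verbatim unweighted mode is kept behind
  `weighted_error_mode="verbatim"`).  The replacement rule (swap a node for
  its children when that lowers the weighted error) is applied through an
  exact subtree recursion, so the result attains the minimum over *all*
  refinements of the current pruning — a purely local parent/children sweep
  can miss improvements that only appear two levels down.  Tests verify the
  optimum against exhaustive enumeration of every pruning on small trees.
* **Selection.** Each query starts at the pruning node with the smallest
  best-class lower bound (vacuous nodes rank first), then descends choosing
  children with probability proportional to their unqueried leaf count.
  Bounds cannot change within a batch (labels arrive only at its end), so
  ties break toward nodes not yet visited in the current batch, then larger
  remaining pool content, then lower node index: a 20-sample batch spreads
  over up to 20 distinct uncertain regions instead of draining one subtree
  of near-duplicate neighbours — selecting many samples from one small area
  is precisely what hierarchical sampling is meant to avoid.
* The loop stops when the pool is empty, an iteration budget is reached, or
  an optional target RMSE is met.

## Ensemble

Hard assignment for training subsets, soft posterior-weighted combination at
prediction time.  All local models share the per-ensemble target scaling so
the fused mixture lives on one scale; local GPs are zero-mean on those
globally centered targets.  Per-component constant offsets (local
intercepts) were implemented and rejected: for a non-stationary component
(the production hump) they pull interpolation gaps toward the component
mean, which measured worse on held-out data, and the marginal likelihood
cannot select against them because the in-sample mean always fits better.

For gating and assignment the mixture's covariances are blended toward the
pooled covariance with weight `0.1·m/n_k`: early in the loop a component may
hold barely more samples than the input dimension, and its ML covariance is
then a near-singular needle — enormous density inside a thin slab, none for
the rest of its own phase — which misroutes queries to a neighbouring local
model.  The blend vanishes as components fill up and never touches the EM
estimates themselves.

Per-component posterior variances are exposed in the prediction trace but
not combined; only the posterior means are fused.

The ensemble (mixture + local GPs) is refitted from scratch after every
query round: labeled sets are small, refits are cheap, and it keeps the
phase partition consistent with all labels seen so far.

## Synthetic fed-batch generator

The generator emulates a multiphase penicillin fermentation; it is a
simplified Bajpai–Reuss-type skeleton, not a numerical replica of any
specific simulator, and absolute benchmark values are therefore comparable
only within this package.

* **Kinetics** (states X biomass, S substrate, P product, V volume):
  Contois growth `μ = μ_max S/(K_X X + S)`; *non-growth-associated*
  production — a repression factor `1/(1 + (μ/μ_crit)^8)` keeps synthesis
  off while the culture grows fast and switches it on smoothly when growth
  slows mid-way through the fed batch; substrate-saturated production with
  weak inhibition; autolysis at low substrate; first-order product
  hydrolysis; feed dilution.  Defaults give a ~0.9 g/L product hump over a
  400 h batch sampled every 0.5 h (800 samples).
* **Three phases** (batch growth to 70 h, tapered fed-batch production to
  220 h, starvation/decline after) appear in the channels as stepped
  pH/temperature setpoints, a feed-rate profile, and biomass-tracking
  agitation/aeration.  The setpoint steps are sized so the phases are
  unambiguous clusters for the mixture model yet close enough in input
  space that a single global GP has to smear the feed-cut kink across the
  phase boundary — the regime where local models genuinely pay.
* **Noise**: controlled channels carry AR(1) wander (sensor drift,
  controller cycling, pump variability; autocorrelation 0.98 per 0.5 h
  step) plus white measurement noise with sd = 1% of each channel's
  noiseless range.  Both scale with `noise_scale`, so the noiseless state
  trajectory is bit-identical across seeds and `noise_scale=0` makes the
  whole dataset seed-independent.
* **Nonlinearity guarantee**: the product hump is driven by the unmeasured
  substrate state through the repression switch, so a global *linear*
  regression of y on u1..u7 leaves ≈30% of the variance unexplained
  (asserted > 20% in tests) while y remains a smooth function of the
  channels — within the fed-batch phase the volume ramp encodes time, so
  nonparametric models can recover the hump.
* **Default protocol sizes** (one simulated batch of 800 samples, 400/400
  alternating train/test split, 8 initial labels, 20 queries × 7 iterations,
  10 repeat seeds, 150-node pruning, K = 3) are the package's reference
  study conditions; the full four-variant benchmark at these sizes runs in a
  few minutes on one CPU.

**What passing tests show — and don't.**  The generator provides a smooth,
noise-controlled, perfectly three-phase process with a stationary
input→quality mapping and abundant ground truth.  Results on it demonstrate
the *relative* behaviour of the four variants under label scarcity and the
correctness of every algorithmic component against independent oracles.
They do not demonstrate robustness to batch-to-batch variation, sensor
faults, drifting kinetics, controller feedback loops, or real assay noise in
y — none of which the generator emulates — and absolute RMSE/TP values carry
no meaning outside this benchmark.

## Known limitations

* Isotropic kernels only; no ARD, sparse approximations or non-Gaussian
  likelihoods.
* The classification-style confidence bounds collapse on single-label pure
  nodes (see above); the sampler inherits this optimism from the printed
  half-width formula.
* The ensemble's advantage over a global GP is a sparse-label phenomenon;
  with dense labels the two converge on this benchmark.
* `run_protocol` isolates cell failures but does not retry them; a failed
  (variant, seed) cell simply appears in the report's failure list.
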