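# Methods

`netrecon` benchmarks how well directed regulatory networks can be
recovered from time-course data of the kind obtainable in vivo: few
subjects, few time points, substantial measurement noise, and no knockout
or perturbation library. Everything is self-generated, so the ground truth
is always known; the pipeline is generate → simulate → infer → aggregate →
score, with every stage reproducible from a master seed.

## Reference networks

Ground truth is a directed signed graph on `n` nodes, stored as an integer
adjacency matrix over {−1, 0, +1} where entry `(i, j) ≠ 0` means node `j`
regulates node `i`. Generated networks have exactly the requested number of
off-diagonal edges (edge density `E / N(N−1)`), no self-loops, and three
topological biases meant to mimic biological regulatory circuits:

- **hubs** — edge sources are drawn with probability proportional to
  (out-degree + 1), a preferential-attachment rule that right-skews the
  out-degree distribution;
- **modules** — nodes are partitioned round-robin into `n_modules`
  (default 3) blocks and an edge's target falls inside the source's module
  with probability 0.8 (configurable);
- **signs** — each edge is inhibitory with independent probability
  `p_inhibition` (default 0.3).

These are deliberate parameterizations of qualitative properties
(sparseness, scale-free-like connectivity, clustering); no attempt is made
to replicate any specific simulator's topology algorithm, and the module
count, hub bias and sign balance are calibration choices.

## Fuzzy-logic dynamics (the synthetic-data generator)

Expression trajectories live on a normalized [0, 1] scale. At each internal
Euler step the target state of node `i` is resolved from its regulators by
fuzzy logic: activators combine by fuzzy OR (`max`), inhibitors by fuzzy
NOT of fuzzy OR, and the two factors multiply —

    T_i = clamp01( act_i · (1 − max_{j∈inhibitors} x_j) ),
    act_i = max_{j∈activators} x_j,  or 0.5·basal_level if no activators.

The state then moves toward the target through a sigmoid-modulated step
weighted by a per-node time constant:

    x_i ← x_i + (dt/τ_i) · (σ(g·(T_i − x_i)) − ½) · 2 · |T_i − x_i|.

The signed logistic factor has the sign of `T_i − x_i` and magnitude ≤ 1,
and `τ_i` is truncated below at `tau_mean/10`, so with `dt = 0.1` the state
moves monotonically toward the target and never leaves [0, 1]. This is the
simplest Mamdani-style composition consistent with "fuzzy regulation
resolved to a target, approached sigmoidally with synthesis/degradation
kinetics"; it is intentionally a *different model class* from every
inference engine applied to it, so no method ever enjoys a same-model
advantage.

Parameters and defaults: `tau_mean = 5`, `tau_sd = 1` time units (Gaussian,
truncated; these set how fast nodes respond), `sigmoid_gain = 10`
(step sharpness), `basal_level = 0.5` (unregulated nodes relax to 0.25),
`dt = 0.1`, `n_steps = 500` (a 50-time-unit horizon, roughly ten time
constants, sampled from t = 0 so transients are retained). Initial states
are uniform on [0, 1] per course. The kinetic means are calibration
choices; nothing downstream is sensitive to their exact values so long as
the sampled horizon spans the transient.

Sampling keeps `m` indices evenly spaced between the first and last
simulated points (both endpoints always included). Noise is zero-mean
Gaussian, scaled per node: sd = `fraction` × the sd of that node's
noise-free trajectory ("20% noise" means fraction 0.2). An alternative
reference scale (fraction of the node's dynamic range) is available via
`add_noise(..., reference="range")`; per-node sd is the default because a
dimensionless noise percentage needs a signal scale and the trajectory sd
is the least arbitrary one. Noisy values are clamped at 0 (expression
cannot be negative).

What the generator does *not* emulate: delay or stochastic (Gillespie)
kinetics, unobserved regulators, measurement-platform artifacts
(saturation, batch effects), or uneven sampling. Passing benchmarks here
therefore bounds what these methods can do under idealized in-silico
conditions, not what they will do on real assay data.

## Linear-ODE identification

The working model is the linear rate equation dX/dt = A·X(t) (+ B·u(t)
under external perturbation), identified row by row: the regulators of
node `i` are the support of row `i` of A, so each row is an independent
linear regression. Two data layouts feed those regressions:

- **gradient**: response = finite-difference rate estimates (numpy's
  `gradient`, i.e. three-point Lagrange central differences on possibly
  uneven grids, one-sided at the ends), design = the states;
- **integral**: the equation integrated from `t_0` to each `t_f` —
  response row `f` = `X(t_f) − X(t_0)`, design = trapezoidal cumulative
  integrals. Integration smooths noise instead of amplifying it, which is
  the point of the integral variant.

Multiple courses are conditioned per course (optional ln(x + 1e−6) and
per-node z-scoring; a first-order-hold interpolator is available but off by
default) and row-concatenated, the integral response resetting at each
course's own initial condition.

Three feature-selection routes control the collinearity of the regressors:

1. **Stepwise truncation** — forward-backward selection by partial-F
   tests: recruit the candidate with the smallest p-value while it is below
   `p_enter` (default 0.05), drop any recruited term whose p-value rises
   above `p_remove` (default 0.10), repeat to a fixed point; OLS
   coefficients on the final support, no intercept (the rate equation has
   none). Ties in p-value (exact fits) break toward the stronger RSS
   reducer, and residuals below 1e−9 of the response sum of squares count
   as exact fits so that numerically perfect models neither recruit
   spurious terms nor shed needed ones.
2. **PLS projection** — PLS1 regression (NIPALS, uncentered scale) onto
   `k` latent vectors, with `k` chosen per row by either the broken-stick
   rule applied to the X-variance shares of a full-rank preliminary fit
   (fractions renormalized and sorted) or Bartlett's trailing-eigenvalue
   equality test on the design covariance spectrum; predictors are then
   screened by VIP (variable influence on projection, Σ VIP² = p) and the
   survivors refit by OLS. The refit removes projection shrinkage from the
   reported weights. VIP is computed on unit-variance predictor columns —
   importance scores are meaningless across heterogeneous scales — while
   the refit uses the raw columns so weights keep their units. PLS1
   (one response at a time) rather than a joint multi-response fit keeps
   the rows of A decoupled, matching the row-wise model.
3. **TSNI-integral** — forward-only stepwise regression on the integral
   layout, stopping at `p_enter` or at a hard per-row cap
   (`max_regressors`, the sparseness knob); integrated perturbation
   columns, when present, are always kept and their coefficients reported
   as the gain matrix B.

Continuous weight matrices become signed networks by quantile pruning:
threshold at the empirical `q`-quantile of |nonzero weights|, keep edges at
or above it, sign = sign of the weight. `q = 0` keeps every nonzero weight;
the operation is monotone in `q`.

Numerical notes. Broken stick is floored at one retained component (a
zero-component model is vacuous); Bartlett's test requires more samples
than predictors and falls through to `p − 1` components if every equality
hypothesis is rejected; covariance eigenvalues are clipped at 1e−12 before
logs; rows with (numerically) constant response yield empty support rather
than an error.

In the noise-free identifiability checks the projection route is run with
the VIP screen off (`vip_threshold = 0`): with exact data the OLS refit
already separates true terms (O(1) coefficients) from null terms
(coefficients at machine zero, flushed to exact zero), so screening adds
nothing and its threshold would otherwise be the only obstacle to exact
support recovery on tiny systems (with `p` predictors Σ VIP² = p, so on a
two-predictor row one VIP is almost surely below 1.0 even when both
predictors are real).

## Time-delay information-theoretic inference

A simplified re-implementation of the three-step time-delay approach:

1. **Initial change (IcE)** — per node, the first index whose fold change
   relative to the first observation crosses `tau_up` (> 1) or `tau_down`
   (< 1). Implemented as the symmetric ratio `x_j / x_0` tested in both
   directions (relative increase or decrease). States are lifted by a
   small positive offset first since fold change needs a positive baseline.
2. **Lagged MI with a bootstrap null** — for each ordered pair with
   IcE(source) ≤ IcE(target) (temporal precedence), the maximum over lags
   1..`max_lag` of the mutual information MI = H(x) + H(y) − H(x, y)
   between the source series and the lag-shifted target, entropies from
   equal-width discretization into `n_bins` (default 4) in base-2 logs.
   An edge is kept when its MI exceeds the (1 − α) quantile of a null
   distribution built by resampling the source series with replacement
   `n_bootstrap` times.
3. **DPI pruning** — in every directed triangle a→b→c with shortcut a→c,
   the shortcut is removed when MI(a,c) < min(MI(a,b), MI(b,c)) ·
   (1 − tolerance), all triangles judged simultaneously against the
   original MI values.

Edge signs come from the lagged Pearson correlation at the maximizing lag;
scoring ignores them, so this is informational only. Equal-width binning
(not a kernel estimator) was chosen for determinism; defaults
(`tau_up = 1.2`, `tau_down = 0.8`, `max_lag = 3`, `n_bootstrap = 100`,
α = 0.05, DPI tolerance 0.15) are calibration choices for ten-node-scale
courses.

## Consensus, scoring, and tuning

**Quorum consensus.** Networks inferred from individual courses are
aggregated edge-wise: an edge enters the consensus when present in at least
`k` of `M` inputs (sign = majority, ties → +1). `k` is chosen by exhaustive
scan for the maximum F against the reference, smallest maximizer on ties.
Since consensus edges shrink monotonically in `k`, the scan covers a
monotone family.

**Scoring** is direction-only (an edge counts when source and target match,
sign ignored — the field's convention) over off-diagonal entries by
default: PPV = TP/(TP+FP), recall = TP/(TP+FN), F = harmonic mean. The PPV
of an empty prediction is defined as 0, which forces F to 0 and keeps
vacuous output from scoring well. Diagonal comparison can be switched on
for references that contain self-regulation.

**Tuning.** Thresholds matter more than model form in this regime, so
parameters (p_enter, p_remove, VIP cut, pruning quantile, sparsity cap) are
tuned per scenario by constrained simulated annealing: one-parameter
Gaussian proposals clamped to a bounded box, Metropolis acceptance
exp(Δ/T), geometric cooling (T0 = 1, factor 0.95, 200 iterations by
default), objective = median consensus F over the training scenarios.
Proposals are one-at-a-time because the box is small and the objective
cheap. Tuning and evaluating on the same scenarios is optimistic;
`score_scenarios` supports held-out re-scoring, which is the recommended
way to report generalization.

For group aggregation the effective regime found by tuning is permissive
per-course inference — VIP screen off and per-course pruning near the
median weight — so individual networks are dense (high recall, low
precision) and the quorum scan does the false-positive pruning. The
group-benefit checks use exactly that configuration.

## Problem sizes used in the test suite and acceptance script

The shipped checks run at desk scale: 20 replicate networks (one noisy
50-point course each) for the noise-robustness ordering; 6 networks × 10
courses for the aggregation benefit; a scaling ladder at 5, 10, 20 and 50
nodes (densities 40, 21, 8, 3%) with 8 courses each; and the headline tuned
consensus experiment at 10 replicate 10-node networks (10–30% density),
10 courses × 10 time points, 20% noise, with a 60-iteration annealing
budget (25 iterations and 5 networks in the test-suite variant). These
sizes are the package's own choices for a reproducible desk-scale study;
larger replications only tighten the medians.

## Known limitations

- The fuzzy-logic simulator is a re-implementation of the *style* of
  logic-based generators, not any specific tool; absolute performance
  numbers shift with simulator details even when the qualitative findings
  (projection ≳ truncation under noise, consensus ≳ single course, decline
  with size/sparsity) are stable. In particular the tuned-consensus
  operating point here sits at higher recall / lower precision than the
  historical reference experiment it mirrors, at a comparable F score.
- Signed-edge accuracy is not scored anywhere (direction only).
- The TD route omits the original's kernel MI estimator and two-phase DPI
  scheduling; it is a faithful simplification, not a port.
- Bartlett's rule needs more rows than predictors, so on very short
  courses only the broken-stick rule is applicable per course.
- Tuning on the evaluation scenarios (the default protocol here, mirroring
  the benchmark design) overstates attainable performance; use held-out
  scenarios for honest generalization estimates.
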