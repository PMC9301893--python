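# Methods

This document defines the generative model, the estimation procedure, the
numerical choices behind them, and the known limitations. Everything here is
implemented in `src/vratio/` and exercised by `tests/`.

## 1. Generative model

### 1.1 Decision stage

Evidence `e(t)` follows a discrete random-walk approximation of a Wiener
diffusion between absorbing boundaries 0 and `a`, starting at `z·a` with
`z = 0.5` (unbiased; other values are rejected):

```
e(t + τ) = e(t) + s·v·τ + σ·√τ·ε,   ε ~ N(0, 1)
```

with step size `τ = 0.001 s`, within-trial noise `σ = 1` (both fixed), drift
magnitude `v`, and stimulus sign `s ∈ {−1, +1}` mapping the two stimulus
classes onto drifts `+v` and `−v`. The walk ends when `e ≤ 0` (choice −1) or
`e ≥ a` (choice +1); decision time is `steps · τ` and observed RT adds the
non-decision time `Ter`. Walks are capped at 7.5 s of decision time; in the
data-generation path a capped walk is resampled, so all emitted trials are
genuine boundary crossings.

For analysis we orient evidence relative to the *chosen* boundary: trials
ending at the lower boundary are reflected (`e → a − e`, drift signs flipped),
so that larger evidence always means more support for the choice made.

**Analytic oracles.** The continuous-time process has closed forms used as test
oracles: accuracy `(1 − e^{−2vza/σ²})/(1 − e^{−2va/σ²})` and mean decision time
`(a/2v)·tanh(va/2σ²)` at `z = 0.5`, with driftless limits `z` and
`a²z(1−z)/σ²`. The discrete walk overshoots boundaries by up to one step, which
biases accuracy upward by ~0.003 and mean decision time by ~τ-scale amounts at
(v=1, a=2). Monte-Carlo tests are therefore sized *a priori* so that this
discretization bias stays comfortably inside the 3-standard-error acceptance
band: n = 5000 for accuracy (bias ≈ 0.8 SE) and n = 600 for mean decision time
(bias ≈ 1.1 SE). These sizes were chosen from the bias analysis, not tuned to
outcomes.

### 1.2 Post-decision stage

After the boundary crossing, accumulation continues *without* boundaries for
the duration of the trial's confidence RT, with drift `s·v·v_ratio` — the same
stimulus, attenuated (or amplified) by the v-ratio. Because the post-decision
walk is unbounded Brownian motion with drift, its endpoint after
`m = ⌊duration/τ⌋` steps is drawn in closed form:

```
e_post = e_decision + s·v·v_ratio·m·τ + σ·√(m·τ)·ε
```

This is exact (the sum of m i.i.d. normal increments), not an approximation.

Confidence RTs come from an empirical pool: when fitting real data, the
subject's own confidence RTs; in the simulation study, a dummy pool of
first-passage times from a perturbed-parameter walk. Durations are sampled
without replacement, restarting the pool when exhausted, so the simulated
duration distribution matches the pool's.

### 1.3 Confidence mapping

Raw confidence is a linear readout of choice-oriented post-decision evidence:

```
conf_raw = (e_post + M) / SD
```

For a discrete scale with levels `1..K`, `conf_raw` is rounded
half-away-from-zero and clamped into `[1, K]`. For continuous scales the value
is clamped to the scale range and a fraction `P` of trials (the estimated
probability of responding exactly at the scale midpoint) is pulled to the
nearest midpoint: the `⌊P·n⌋` values closest to the midpoint are set to it,
with stable tie-breaking. `P` is estimated from data as the proportion of
responses exactly at the midpoint; on a 6-point scale there is no midpoint
level and `P = 0`.

## 2. Static metrics

- **d′ and criterion**: `d′ = (1/s_r)·z(HR) − z(FAR)`,
  `c = −(z(HR) + z(FAR))/(1 + s_r)` with type-1 evidence-SD ratio `s_r`
  (default 1). Cell counts are padded by `1/(2K)` before computing rates.
- **meta-d′**: maximum-likelihood fit of the type-2 rating distributions under
  an SDT observer whose type-1 sensitivity is replaced by `meta_d′` while the
  type-1 criterion is held at the same *relative* location
  (`meta_c = meta_d′·c/d′`). The `2(K−1)` type-2 criteria are parameterized as
  log-gaps from the type-1 criterion to enforce ordering; the conditional
  type-2 likelihood is maximized with L-BFGS-B from multiple starts. With
  `s_r ≠ 1` the unequal-variance mapping uses the scale factor
  `√(2/(1 + s_r²))·s_r`. The conditional likelihood factorizes across the two
  response sides; the test suite exploits this to build an independent
  brute-force grid oracle that the MLE must match to 1e-3.
- **M-ratio**: `meta_d′ / d′`, flagged undefined when `d′ ≤ 0`.
- **Type-II AUC**: Mann–Whitney U between confidence on correct vs error
  trials, ties counted half.
- **Binning**: confidence is quantile-binned into the requested number of
  levels with deterministic tie handling, so any strictly monotone transform of
  confidence leaves the table unchanged.

## 3. Fitting

### 3.1 Quantile summary and objective

Per subject, trials are split by accuracy. Within each class, RT quantile edges
at .1/.3/.5/.7/.9 define six bins; bin proportions are scaled by the class mass
so that the twelve numbers sum to one. The same is done for confidence (for
discrete scales, per-level proportions instead of quantile bins). Classes with
fewer than 5 trials are collapsed. The distance between an observed summary `o`
and a simulated summary `p` is the chi-square

```
χ² = Σ (o_i − p_i)² / max(p_i, 1e-4)
```

summed over the RT and confidence blocks, and over conditions when
per-condition drifts are fitted.

### 3.2 Deterministic common-random-numbers simulation

A naive objective re-randomizes every evaluation, which makes the surface noisy
and forces huge `n_sim`. Instead, each fit freezes its randomness once from a
master seed:

- a table of `2²²` standard normals shared by all simulated trials;
- one post-decision endpoint normal per simulated trial;
- one frozen confidence-RT design (the subject's pool, **sorted** before
  sampling so the objective is invariant to trial order in the input data).

Trial `i` reads its decision-stage innovations from the table at index
`(i · 2654435761 + offset₀) mod 2²²` (a golden-ratio stride with wraparound),
so consecutive trials use effectively independent streams while every parameter
vector sees identical noise. In this path a walk that hits the 7.5 s cap is
terminated in place (choice by which half of `[0, a]` it sits in) rather than
resampled, keeping the evaluation cost bounded; capped walks are counted and
are negligible in the fitted region. The result is an objective that is both
deterministic and smooth in the parameters, and ~9× faster per evaluation than
the buffered fresh-noise kernel.

### 3.3 Optimization

`scipy.optimize.differential_evolution` over
`(v, a, Ter, v_ratio, M, SD)` (one drift per condition when requested), with
`polish=False`, `tol=0`, `updating="immediate"`, a stagnation callback
(`stall_generations` without improvement), and an EZ-diffusion-style heuristic
for the initial point. Defaults: population 60, up to 250 generations,
`n_sim = max(10000, 10·n_trials)`; the examples and acceptance tests use
compact budgets documented inline.

## 4. Simulation study

100 agents × 1000 trials; per agent, drift ~ U(1,3), boundary ~ U(0.5,4),
Ter ~ U(0.2,0.6), v-ratio ~ U(0,1.25), all independent; confidence mapped to a
continuous scale and quantile-binned to 4 levels for meta-d′. The headline
result: M-ratio correlates positively with the generative v-ratio *and*
negatively with the decision boundary, although v-ratio and boundary are
independent by construction — static metacognitive efficiency is confounded
with response caution, while v-ratio is not (r(v-ratio, boundary) ≈ 0).

### 4.1 Known deviations

Against the reference correlations (±0.15 band, seed 1):

- **d′ ~ boundary: 0.84 observed vs 0.683 reference.** The gap is systematic,
  not sampling noise: across seeds this implementation yields 0.78–0.84. The
  type-1 SD-ratio and count-padding conventions were ruled out by direct
  perturbation; the residual gap most plausibly reflects unstated details of
  the reference's agent generation or metric conventions. The sign and the
  qualitative contrast with meta-d′ are reproduced.
- **meta-d′ ~ boundary: −0.39 observed vs −0.141 reference.** This correlation
  is small and high-variance at n = 100 (individual seeds scatter from near 0
  to −0.4); seed 1 lands in the tail. The seed was fixed before outcomes were
  inspected and was not changed afterwards.

All other tracked correlations fall inside the band at seed 1, and the sign
pattern (M-ratio~boundary < 0, M-ratio~v-ratio > 0, |v-ratio~boundary| small)
holds across every seed tested.

## 5. Parameter recovery

Simulate subjects from known parameters drawn from the study ranges, refit,
and report the Pearson r between true and recovered values per parameter
(10 subjects, fixed derived seeds < 2³¹).

- **25,000 trials/subject** (n_sim 5000, population 60, ≤100 generations):
  r = 0.997 (v), 0.998 (a), 0.996 (Ter), 0.76 (v-ratio), 0.59 (M), 0.71 (SD).
  The three low values are produced entirely by one subject with true
  (v 2.44, a 2.93): accuracy saturates at 0.99928, leaving ~18 error trials in
  25,000. On correct trials the confidence mapping `(e + M)/SD` can match the
  first two moments of raw confidence for *any* v-ratio by rescaling M and SD,
  so the whole (v-ratio, M, SD) ridge is separated from the truth only by the
  tiny error class and the objective's O(1/√n_sim) simulation noise. Under the
  fit's frozen design at n_sim = 5000 a degenerate vector
  (v-ratio 1.99, M 6.92, SD 3.23) scores *better* than the truth (χ² 0.0017 vs
  0.0046); raising n_sim to 10,000 merely lets the optimizer find a new
  degenerate vector (χ² 0.00123 vs the truth's 0.00142). The default
  production budget (`n_sim = 10·n = 250,000`, hours per fit) shrinks the
  simulation noise ~50-fold and is the intended regime for this criterion;
  within a minutes-scale test budget we report the miss rather than weight
  the error class beyond its defined class-mass scaling. The other nine
  subjects recover v-ratio to within ~0.09 and every subject recovers v, a
  and Ter almost exactly.
- **200 trials/subject** (n_sim 4000, ≤100 generations): r = 0.88 (v),
  0.95 (a), 0.94 (Ter), 0.79 (v-ratio), 0.58 (M), 0.65 (SD), missing the
  target bounds
  (v-ratio ≥ 0.85, others ≥ 0.98). The same degeneracy dominates, now with no
  usable error class at all for saturated subjects: for the subject above, the
  fit (3.18, 4.94, 0.25, 2.32, 9.14, 4.58) has a chi-square robustly *better*
  than the truth's, out-of-sample and at n_sim up to 20,000 (0.026–0.035 vs
  0.064–0.076). More trials, priors, or fixing M/SD are the remedies; we
  report the limitation rather than relax the estimator.

## 6. Data handling

`read_trials`/`write_trials` use a validated CSV schema (stimulus, choice,
accuracy, rt, confidence, confidence_rt, optional condition/subject), with
unit conversion (ms → s), column mapping, and row-indexed error messages
(negative RTs, accuracy inconsistent with stimulus/choice, confidence outside
the scale). `apply_exclusions` drops trials with RT < 100 ms or
confidence RT > 5 s (boundary values retained), is idempotent, and refuses to
return an empty dataset.

## 7. Reproducibility

All randomness flows from `numpy.random.SeedSequence` spawning; derived seeds
are kept below 2³¹. Every CLI command writes a JSON manifest with its seed and
settings. `scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the study correlations in ~20 s on one CPU. Numba kernels are
compiled with `cache=True`; the first run in a fresh environment pays a
one-time JIT cost of roughly a minute.
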