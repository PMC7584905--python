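# Methods

## The judgment models

All five models map a scenario to the probability that one actor's action is
judged morally acceptable. The three utility-comparing models share the
logistic choice rule

    P(acceptable) = 1 / (1 + exp(τ·ΔU + β))

where ΔU is the model's utility comparison, the temperature τ scales how
strongly the comparison drives judgment, and the bias β sets which way
judgments err when the utilities are about equal. β sits inside the exponent
(a logistic intercept): an additive term outside the logistic could leave
[0, 1], and the intercept form is the standard softmax parameterization.

- **Universalization** compares the hypothetical world in which nobody acts
  with the one in which all interested parties act: ΔU = U(0) − U(m). By
  default m = n_i + 1 — the judged actor is counted alongside the n_i
  interested parties, matching the elicitation design in which utilities are
  probed at N + 1 (grid {1, 3, 8, 9, 14, 20} for n_i ∈ {0, 2, 7, 8, 13, 19});
  `include_actor=False` switches to m = n_i.
- **Outcome** uses the marginal actor at the current actual count:
  ΔU = U(n_a) − U(n_a + 1); n_a = 0 throughout these designs.
- **Pessimistic outcome** substitutes n_a := n_i, asking whether this actor
  could be the pivotal straw: ΔU = U(n_i) − U(n_i + 1). It dips only where
  the utility curve is locally decreasing — inside the harm range.
- **Rule** returns p with no rule present and 1 − p with one; it consults
  neither n_i nor U.
- **Norm** is a logistic in the prohibitive-norm proportion:
  P = 1/(1 + exp(τ·(n_p/n − θ))). The exponent is written as a *centred*
  difference so that θ ∈ (0, 1) is literally the proportion at which an agent
  becomes more likely than not to adopt the norm; an uncentred additive θ
  could not play that role. When the norm model is evaluated over an
  interested-party grid (`predict_curve`), n_p is read as n_i — interested
  parties who refrain are interpreted as subscribing to a norm — which gives
  the model its indirect n_i-sensitivity while leaving it provably blind to
  the utility curve.

Probabilities are clamped to [1e−12, 1 − 1e−12] so Bernoulli log-likelihoods
stay finite; the logistic is evaluated through `scipy.special.expit`, which
saturates rather than overflows.

A useful identity used by the fitter and the tests: negating τ while
reflecting U about any constant leaves the universalization probability
unchanged. Consequently the *coding direction* of a utility curve (high-good
1→0 vs step 0→1) is absorbed by τ's sign and is not an extra degree of
freedom.

## Utility curves

Curves are tabulated on integer actor counts 0..n_max (actors are counts; no
interpolation at evaluation time). Constructors cover the three canonical
dilemma families:

- *idealized threshold*: plateau `u_high` up to `harm_onset`, plateau `u_low`
  from `collapse_point`, linear descent between. The vignettes pin down only
  the plateaus; the linear interior is a deterministic convention and is
  never probed by the study grids.
- *aggregation*: U(n) = −n·loss (each act adds the same harm).
- *coordination*: high utility at n = 0 and n = n_total, low in between.

`classify_dilemma` recovers the family from shape alone, checking
aggregation, then coordination, then threshold (first match wins, a fixed
order that breaks degenerate ties), with an absolute tolerance (default
1e−9) for "flat" and "equal".

Two curves feed the fits:

- the **idealized fit curve**: 0 below the condition's collapse point, 1 at
  or above it. Its essential feature is constancy on each side of the
  threshold; by the sign identity above, the placement of the step inside
  the (never-probed) harm range and the 0/1 direction are immaterial.
- the **empirical curve**: mean elicited rating of U(n) − U(0) at each probed
  n, anchored at U(0) = 0, linearly interpolated between probes, with no
  extrapolation beyond the largest probe.

## Synthetic participants

The generator emulates a repeated-measures two-condition design: each
participant is assigned one harm-threshold condition (`4_7` or `10_13`,
n_total = 20) uniformly at random and judges all six interested-party levels
{0, 2, 7, 8, 13, 19}. The population is a mixture of uniform-acceptable
responders, uniform-unacceptable responders, and universalizers
(default 0.55 / 0.18 / 0.27, matching the observed partition of adults).
Universalizers draw independent Bernoulli judgments from the
universalization probability under the condition's idealized curve.

The default universalizer parameters are τ = 6, β = −3, i.e. ≈ 0.95
acceptance below the threshold and ≈ 0.05 above it. These were chosen to
match the near-ceiling/floor plateaus that the non-uniform subgroup exhibits
empirically; a convenient side effect is that a universalizer almost never
produces a uniform response pattern by chance (< 0.2%), so the
generator → classifier round trip recovers the mixture fractions.

Utility ratings are simulated as a mean curve plus truncated-Gaussian noise
on the −50..50 scale (default sd 10, a realistic single-item rating spread;
the spread is a free simulation parameter, as only mean curves are observed
empirically). The default mean curve is *sloped-plateau*: slightly positive
(+8 → +4) with a shallow negative slope below the threshold, strongly
negative (−30 → −40) with a shallow slope above it — the empirically
observed deviation from the idealized flat-plateau shape. With sd = 0 the
mean is clipped to the scale instead (truncation is undefined at zero
spread).

What the generator does **not** emulate: vignette comprehension and the
attention-check exclusions applied to real samples, within-participant order
effects (judgments are exchangeable given the strategy), and any
heterogeneity of (τ, β) across universalizers. Passing tests therefore show
that the pipeline is correct under the stated mixture model, not that real
populations satisfy it.

Reproducibility: participant i draws from
`SeedSequence(master_seed, spawn_key=(namespace, i))`, so datasets are
byte-identical across runs and stable under changes of `n_participants` up
to the shared prefix.

## Fitting and model comparison

A single parameter set is fitted jointly to all conditions (records weighted
equally), to the *non-uniform* participants only — uniform responders carry
no information about (τ, β) and are the signature of the outcome/rule
family. Free parameters: (τ, β) for universalization, outcome and
pessimistic; p for rule; (τ, θ) for norm. AIC = 2k − 2·lnL.

The optimizer is deterministic: a coarse grid — τ over 33 log-spaced
magnitudes in [0.01, 50] of both signs plus 0; β linear over [−10, 10]
(21 points); θ linear over [0.05, 0.95] (19 points) — followed by
Nelder–Mead refinement from the best grid point. `converged` is true when
the refined optimum is at least as good as the best grid point (within
1e−9). The rule model's likelihood has a closed-form maximum (the clamped
mean acceptance rate); an all-identical dataset puts it on the clamp
boundary and is flagged `converged=False` rather than raising. Since each
record enters the likelihood only through a scalar feature, records are
aggregated to unique feature values before optimization, making fits
O(grid × distinct cells) rather than O(grid × records).

## Contingency statistics

Implemented from first principles so printed values are recomputable:
Pearson's 2×2 χ² via n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), with Yates'
correction reducing |ad−bc| by n/2 (floored at zero); Cramér's V = √(χ²/n)
(= φ for 2×2), computed from whichever statistic was reported; McNemar's
test of changes on the discordant counts, with the continuity-corrected
statistic (|b−c|−1)²/(b+c) also floored at zero (conventions differ when
b = c; the floor keeps the corrected statistic ≤ the uncorrected one).
p-values are upper-tail χ² with 1 df. V and φ are rounded to two decimals
at presentation only. The continuity-corrected McNemar p tracks the exact
two-sided binomial p to within 0.003 for all discordant totals ≥ 25, which
the property suite checks.

## Problem sizes and numerical choices

The simulation studies use: 500 participants for (τ, β) recovery (true
τ = 3, β = −0.5; recovered within ±0.5 and ±0.3); 50 replicates × 300
participants for five-way AIC model recovery; 20 replicates × 300
participants (plus 100 raters per condition) for the
empirical-vs-idealized comparison, with generating τ = 0.15 on the −50..50
utility scale (utility gaps of ~30–40 scale units then yield judgment
probabilities in the 0.7/0.01 range, comparable to the unit-scale regimes);
10,000 participants for the mixture round trip. These sizes give stable
statistics at desk scale; the whole acceptance run completes in seconds.

Degenerate inputs are rejected with named-field messages (curve/scenario
bound violations, empty designs, zero-margin tables, zero discordant
totals); fitting an all-uniform dataset is reported as having nothing to
fit rather than producing a spurious estimate.

## Known limitations

- Group-level fits only; no hierarchical or per-participant (τ, β).
- No confidence intervals for fitted parameters or effect sizes.
- The "everyone" utility scope aggregates the actor's and others' curves by
  unweighted summation; no bargaining-style aggregation is attempted.
- The norm model's n_p ≈ n_i proxy is an interpretive assumption, not a
  fitted quantity.
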