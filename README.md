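# universalize

Computational models of moral judgment in **threshold problems** — collective-action
dilemmas in which the aggregate utility `U(n)` of `n` people taking an action is
flat while few act, collapses within a critical interior range of actor counts
(the *harm threshold*), and is flat again beyond it. The canonical vignette: up
to 4 of 20 vacationing fishermen can use a new, more effective hook with no
effect on the fish population, but once 7 use it the population goes extinct.
Is it morally acceptable for one person to use the hook, given that `n_i`
others are *interested* in doing so?

The package is aimed at computational cognitive scientists who want to
simulate, fit, and compare formal models of such judgments.

## Models

Five candidate accounts of the probability that one actor's action is judged
morally acceptable, all sharing a logistic ("softmax") choice rule with
temperature τ and bias β:

| model | comparison | sensitive to `n_i`? | to `U`? |
|---|---|---|---|
| universalization | `U(0) − U(n_i + 1)` — the world where nobody acts vs the world where every interested party (plus the judged actor) acts | yes | yes |
| outcome | `U(n_a) − U(n_a + 1)` — the marginal actor at the current actual count | no | yes |
| pessimistic outcome | `U(n_i) − U(n_i + 1)` — assumes every interested party will eventually act | yes | yes |
| rule | `p` if no rule, `1 − p` if a rule is present | no | no |
| norm | logistic in the prohibitive-norm proportion `n_p/n` vs a threshold θ | no (only via `n_p`) | no |

e.g. `P_univ(acceptable) = 1 / (1 + exp(τ·(U(0) − U(n_i+1)) + β))`.
Only universalization predicts an interaction between the number of interested
parties and the *location* of the harm threshold: acceptability drops fastest
where `n_i` crosses the threshold.

The package provides utility-curve constructors for threshold, aggregation,
and coordination dilemmas (plus a shape classifier); a synthetic-participant
generator mixing uniform responders with universalizers; group-level
maximum-likelihood fitting of the choice parameters (deterministic grid search
plus Nelder–Mead refinement) with AIC comparison; empirical utility curves
built from elicited `U(n) − U(0)` ratings on a −50..50 scale; response-profile
classification; and first-principles contingency statistics (χ² with Yates
correction, Cramér's V, McNemar's test).

## Worked example

Simulate the default design (600 participants, conditions `4_7` and `10_13`,
interested-party grid {0, 2, 7, 8, 13, 19}, strategy mixture
0.55 / 0.18 / 0.27), then fit all five models to the non-uniform responders:

```sh
universalize simulate --seed 11 --out run
universalize compare run/judgments.csv --ratings run/ratings.csv --out run
```

```
           model         aic  log_likelihood  converged                                                     params
universalization  385.054524     -190.527262       True    {"tau": -6.060924642416666, "beta": -3.008154768285725}
            norm  742.013131     -369.006566       True   {"tau": 8.547302462752445, "theta": 0.37932866783864905}
            rule 1416.016327     -707.008163       True                         {"p_no_rule": 0.49901960784313726}
         outcome 1418.016327     -707.008163       True {"tau": -0.00195980840921402, "beta": 0.00392156994342804}
     pessimistic 1418.016327     -707.008163       True {"tau": -0.00195980840921402, "beta": 0.00392156994342804}
```

Universalization — the model that generated the non-uniform responders — wins
the AIC comparison by a wide margin. The fitted temperature is negative
because the default fit uses the 0-below / 1-above idealized step coding;
jointly flipping τ's sign and the 0/1 coding leaves the model unchanged, so
this is the generating τ = 6 (and β ≈ −3) recovered. The outcome and rule
models are blind to `n_i` and collapse onto the marginal acceptance rate
(≈ 0.5 here); the norm model (with `n_p` read as `n_i`) captures the decrease
in `n_i` but not its dependence on the threshold's location, and lands in
between.

The same dataset's response profiles, in the library:

```python
>>> from universalize import classify_profiles, read_judgments
>>> classify_profiles(read_judgments("run/judgments.csv")).proportions
{'uniform_acceptable': 0.562, 'uniform_unacceptable': 0.155, 'non_uniform': 0.283}
```

`universalize reproduce` recomputes the published contingency statistics from
their printed counts:

```
Cramer's V, adults low vs high interest (chi2=62.0, n=608)    computed 0.3193  printed 0.32  ok
Cramer's V, threshold vs no-threshold (chi2=58.61, n=250)     computed 0.4842  printed 0.48  ok
Cramer's V, children low vs high interest (chi2=6.85, n=185)  computed 0.1924  printed 0.19  ok
...
```

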