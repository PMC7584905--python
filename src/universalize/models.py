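"""Candidate models of moral judgment in threshold problems.

Each model maps a scenario to the probability that one actor's action is
judged morally *acceptable*:

- **universalization** — compares the utility of the hypothetical world in
  which nobody acts against the one in which all ``n_i`` interested parties
  act, ``P = logistic(-(tau * (U(0) - U(m)) + beta))`` with
  ``m = n_i (+1 when the judged actor is counted)``;
- **outcome** — compares the current world against one more actor,
  ``U(n_a) - U(n_a + 1)``; insensitive to ``n_i``;
- **pessimistic** — an outcome model that assumes every interested party
  will eventually act, so the marginal actor is evaluated at ``n = n_i``;
- **rule** — acceptability depends only on whether a rule is present;
- **norm** — acceptability depends only on the proportion ``n_p / n`` of the
  population subscribing to a prohibitive norm, via a logistic with a
  threshold proportion ``theta``; insensitive to the utility curve.

The shared logistic choice rule has a temperature ``tau`` (strength of the
utility comparison) and a bias ``beta`` (which way judgments err when the
utilities are about equal).  All probabilities are clamped a hair inside
(0, 1) so downstream log-likelihoods stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .scenarios import DualRoleScenario, ThresholdScenario, UtilityCurve

__all__ = [
    "ChoiceParams",
    "RuleParams",
    "NormParams",
    "MODEL_LABELS",
    "CLAMP_LO",
    "CLAMP_HI",
    "choice_probability",
    "p_universalization",
    "p_outcome",
    "p_pessimistic",
    "p_rule",
    "p_norm",
    "p_universalization_scoped",
    "frustrated_means",
    "predict_curve",
]

#: Model labels used by the CLI and fit results.
MODEL_LABELS = ("universalization", "outcome", "pessimistic", "rule", "norm")

#: Probability clamp keeping Bernoulli log-likelihoods finite.
CLAMP_LO = 1e-12
CLAMP_HI = 1.0 - 1e-12


@dataclass(frozen=True)
class ChoiceParams:
    """Logistic choice parameters: temperature ``tau`` and bias ``beta``.

    Both may take any finite real value; negating ``tau`` while reflecting
    the utility curve about a constant leaves the model unchanged, so the
    sign convention is tied to the utility coding.
    """

    tau: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau) and np.isfinite(self.beta)):
            raise ValueError(f"tau and beta must be finite, got {self.tau}, {self.beta}")


@dataclass(frozen=True)
class RuleParams:
    """Rule-model parameter: the acceptability probability when no rule is
    present (its complement applies when one is)."""

    p_no_rule: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_no_rule <= 1.0:
            raise ValueError(f"p_no_rule={self.p_no_rule} outside [0, 1]")


@dataclass(frozen=True)
class NormParams:
    """Norm-model parameters: temperature ``tau`` and the threshold
    proportion ``theta`` of the population that must exhibit a prohibitive
    norm for an agent to be more likely than not to adopt it."""

    tau: float
    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau):
            raise ValueError(f"tau must be finite, got {self.tau}")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta={self.theta} must lie strictly in (0, 1)")


def choice_probability(argument, tau: float, beta: float):
    """Evaluate the shared logistic rule ``1 / (1 + exp(tau * x + beta))``,
    clamped to ``[CLAMP_LO, CLAMP_HI]``.

    Vectorised over ``argument``; overflow saturates through
    :func:`scipy.special.expit` rather than raising.
    """
    p = expit(-(np.asarray(tau, dtype=float) * np.asarray(argument, dtype=float) + beta))
    return np.clip(p, CLAMP_LO, CLAMP_HI)


# ---------------------------------------------------------------------------
# The five models
# ---------------------------------------------------------------------------

def p_universalization(
    scenario: ThresholdScenario,
    params: ChoiceParams,
    include_actor: bool = True,
) -> float:
    """Universalization: compare the world where nobody acts with the world
    where all interested parties (plus the judged actor, when
    ``include_actor``) act."""
    m = scenario.n_interested + (1 if include_actor else 0)
    if m > scenario.n_total:
        raise ValueError(
            f"universalized world size {m} exceeds n_total={scenario.n_total}"
        )
    delta = scenario.curve(0) - scenario.curve(m)
    return float(choice_probability(delta, params.tau, params.beta))


def p_outcome(scenario: ThresholdScenario, params: ChoiceParams) -> float:
    """Outcome model: marginal utility of one more actor at the current
    actual count ``n_a``; does not read ``n_interested``."""
    if scenario.n_actual + 1 > scenario.n_total:
        raise ValueError(
            f"n_actual+1={scenario.n_actual + 1} exceeds n_total={scenario.n_total}"
        )
    delta = scenario.curve(scenario.n_actual) - scenario.curve(scenario.n_actual + 1)
    return float(choice_probability(delta, params.tau, params.beta))


def p_pessimistic(scenario: ThresholdScenario, params: ChoiceParams) -> float:
    """Pessimistic outcome model: assume every interested party will act, so
    evaluate the marginal actor at ``n = n_i`` ("am I the pivotal straw?")."""
    if scenario.n_interested + 1 > scenario.n_total:
        raise ValueError(
            f"n_interested+1={scenario.n_interested + 1} exceeds "
            f"n_total={scenario.n_total}"
        )
    delta = scenario.curve(scenario.n_interested) - scenario.curve(scenario.n_interested + 1)
    return float(choice_probability(delta, params.tau, params.beta))


def p_rule(scenario: ThresholdScenario, params: RuleParams) -> float:
    """Rule model: acceptability is ``p`` with no rule, ``1 - p`` with one."""
    p = 1.0 - params.p_no_rule if scenario.rule_present else params.p_no_rule
    return float(np.clip(p, CLAMP_LO, CLAMP_HI))


def p_norm(scenario: ThresholdScenario, params: NormParams) -> float:
    """Norm model: logistic in the prohibitive-norm proportion ``n_p / n``
    relative to the threshold ``theta``; invariant to the utility curve."""
    if scenario.n_total <= 0:
        raise ValueError("n_total must be positive")
    frac = scenario.norm_count / scenario.n_total
    p = expit(-(params.tau * (frac - params.theta)))
    return float(np.clip(p, CLAMP_LO, CLAMP_HI))


# ---------------------------------------------------------------------------
# Utility-scope variants (whose utilities matter when universalizing)
# ---------------------------------------------------------------------------

def p_universalization_scoped(
    scenario: DualRoleScenario,
    params: ChoiceParams,
    scope: str,
    include_actor: bool = True,
) -> float:
    """Universalization restricted to a utility scope.

    ``scope="everyone"`` sums the actor's and the other parties' curves;
    ``scope="actor"`` uses the actor's curve alone.
    """
    if scope == "everyone":
        values = tuple(
            a + o for a, o in zip(scenario.actor_curve.values, scenario.others_curve.values)
        )
        curve = UtilityCurve(scenario.n_total, values, kind_label="custom")
    elif scope == "actor":
        curve = scenario.actor_curve
    else:
        raise ValueError(f"unknown scope {scope!r}; expected 'everyone' or 'actor'")
    m = scenario.n_interested + (1 if include_actor else 0)
    if m > scenario.n_total:
        raise ValueError(f"universalized world size {m} exceeds n_total={scenario.n_total}")
    delta = curve(0) - curve(m)
    return float(choice_probability(delta, params.tau, params.beta))


def frustrated_means(scenario: DualRoleScenario) -> bool:
    """Whether universal adoption frustrates the actor's own goal: true iff
    the actor is strictly worse off when everyone acts than when acting
    alone, ``U_j(n_total) < U_j(1)``."""
    return scenario.actor_curve(scenario.n_total) < scenario.actor_curve(1)


# ---------------------------------------------------------------------------
# Predicted judgment curves over a grid of interested-party counts
# ---------------------------------------------------------------------------

def predict_curve(
    model: str,
    scenario: ThresholdScenario,
    params,
    ni_grid,
    include_actor: bool = True,
) -> np.ndarray:
    """Evaluate a model's acceptability probability at each interested-party
    count in ``ni_grid``, all other scenario fields held fixed.

    For the norm model the prohibitive-norm count is set to ``n_i`` at each
    grid point (interested parties who refrain are read as subscribing to a
    norm); the other models leave ``norm_count`` untouched.
    """
    ni_grid = [int(n) for n in ni_grid]
    if any(n < 0 or n > scenario.n_total for n in ni_grid):
        raise ValueError(f"grid values must lie within [0, {scenario.n_total}]")
    if model not in MODEL_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_LABELS}")

    out = []
    for ni in ni_grid:
        s = scenario.with_n_interested(ni)
        if model == "universalization":
            out.append(p_universalization(s, params, include_actor=include_actor))
        elif model == "outcome":
            out.append(p_outcome(s, params))
        elif model == "pessimistic":
            out.append(p_pessimistic(s, params))
        elif model == "rule":
            out.append(p_rule(s, params))
        else:  # norm: n_p approximated by n_i
            from dataclasses import replace

            out.append(p_norm(replace(s, norm_count=ni), params))
    return np.asarray(out)
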