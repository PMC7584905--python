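"""Maximum-likelihood fitting, AIC model comparison, empirical utility
curves, and response-profile classification.

The group-level fit mirrors the quantitative analysis of the judgment data:
participants whose judgments vary across interested-party counts (the
*non-uniform* responders) are pooled, and a single parameter pair is fitted
jointly to both harm-threshold conditions by maximising the Bernoulli
likelihood of their binary judgments under a candidate model.  Models are
compared by AIC = 2k - 2 ln L.

The optimizer is a deterministic coarse grid search (temperature over
log-spaced magnitudes of both signs plus zero, bias over a linear grid)
followed by derivative-free local refinement (Nelder-Mead); there are no
random restarts, so a fit is reproducible from the data alone.

Utility curves for the fit come from one of two sources:

- *idealized*: a two-valued step, 0 below the condition's threshold and 1 at
  or above it (the temperature's sign absorbs the coding direction);
- *empirical*: mean elicited ratings of ``U(n) - U(0)`` at the probed actor
  counts, linearly interpolated between probes, anchored at ``U(0) = 0``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    CLAMP_HI,
    CLAMP_LO,
    MODEL_LABELS,
    ChoiceParams,
    NormParams,
    RuleParams,
)
from .scenarios import UtilityCurve, condition_bounds
from .synthetic_data import DEFAULT_N_TOTAL

__all__ = [
    "SearchConfig",
    "FitResult",
    "PROFILE_LABELS",
    "ProfileSummary",
    "negative_log_likelihood",
    "fit_mle",
    "empirical_utility_from_ratings",
    "make_idealized_fit_curve",
    "aic",
    "classify_profiles",
    "filter_non_uniform",
]

PROFILE_LABELS = ("uniform_acceptable", "uniform_unacceptable", "non_uniform")

#: Free-parameter count per model.
N_PARAMS = {
    "universalization": 2,
    "outcome": 2,
    "pessimistic": 2,
    "rule": 1,
    "norm": 2,
}


def aic(log_likelihood: float, n_params: int) -> float:
    """Akaike information criterion, ``2k - 2 ln L`` (lower is better)."""
    return 2.0 * n_params - 2.0 * log_likelihood


@dataclass(frozen=True)
class SearchConfig:
    """Grid-then-refine search settings for :func:`fit_mle`.

    The temperature grid covers ``n_tau_mag`` log-spaced magnitudes in
    ``[tau_mag_min, tau_max]``, both signs, plus zero; the bias grid is
    linear over ``[-beta_bound, beta_bound]``.
    """

    tau_max: float = 50.0
    tau_mag_min: float = 0.01
    n_tau_mag: int = 33
    beta_bound: float = 10.0
    n_beta: int = 21
    n_theta: int = 19
    refine: bool = True
    refine_tol: float = 1e-9

    def tau_grid(self) -> np.ndarray:
        mags = np.geomspace(self.tau_mag_min, self.tau_max, self.n_tau_mag)
        return np.concatenate([[0.0], mags, -mags])

    def beta_grid(self) -> np.ndarray:
        return np.linspace(-self.beta_bound, self.beta_bound, self.n_beta)

    def theta_grid(self) -> np.ndarray:
        return np.linspace(0.05, 0.95, self.n_theta)


@dataclass(frozen=True)
class FitResult:
    """A fitted model: parameters, log-likelihood, AIC, and provenance."""

    model: str
    params: dict
    log_likelihood: float
    aic: float
    n_observations: int
    converged: bool
    utility_source: str = "idealized"

    def __post_init__(self) -> None:
        k = N_PARAMS[self.model]
        expected = 2.0 * k - 2.0 * self.log_likelihood
        if abs(self.aic - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(f"aic={self.aic} inconsistent with 2k - 2 lnL = {expected}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _record_features(
    df: pd.DataFrame,
    model: str,
    curve_by_condition: Optional[Mapping[str, UtilityCurve]],
    n_total: int,
    include_actor: bool,
) -> np.ndarray:
    """Reduce each record to the scalar the model's logistic consumes.

    universalization: U(0) - U(n_i + 1{actor}); outcome: U(0) - U(1) (the
    actual actor count is 0 in these designs); pessimistic: U(n_i) -
    U(n_i + 1); norm: n_i / n_total (interested non-actors read as norm
    subscribers); rule: 0 (no rule present in these designs).
    """
    if model not in MODEL_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_LABELS}")
    df = df.reset_index(drop=True)
    ni_all = df["n_interested"].to_numpy(dtype=int)
    if model == "rule":
        return np.zeros(len(df))
    if model == "norm":
        return ni_all / n_total

    x = np.empty(len(df))
    for cond, idx in df.groupby("condition").indices.items():
        if curve_by_condition is None or cond not in curve_by_condition:
            raise ValueError(f"no utility curve supplied for condition {cond!r}")
        curve = curve_by_condition[cond]
        vals = curve.as_array()
        ni = ni_all[idx]
        if model == "universalization":
            m = ni + (1 if include_actor else 0)
            if m.max() > curve.n_max:
                raise ValueError(
                    f"universalized world size {m.max()} outside curve support "
                    f"[0, {curve.n_max}] for condition {cond!r}"
                )
            x[idx] = vals[0] - vals[m]
        elif model == "outcome":
            x[idx] = vals[0] - vals[1]
        else:  # pessimistic
            if ni.max() + 1 > curve.n_max:
                raise ValueError(
                    f"n_interested+1={ni.max() + 1} outside curve support "
                    f"[0, {curve.n_max}] for condition {cond!r}"
                )
            x[idx] = vals[ni] - vals[ni + 1]
    return x


def _aggregate(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse records to unique feature values with 1/0 counts."""
    xs, inverse = np.unique(x, return_inverse=True)
    n1 = np.bincount(inverse, weights=y, minlength=len(xs))
    n0 = np.bincount(inverse, weights=1.0 - y, minlength=len(xs))
    return xs, n1, n0


def _nll_cells(p: np.ndarray, n1: np.ndarray, n0: np.ndarray) -> np.ndarray:
    p = np.clip(p, CLAMP_LO, CLAMP_HI)
    return -(n1 * np.log(p) + n0 * np.log1p(-p))


def negative_log_likelihood(
    dataset: pd.DataFrame,
    model: str,
    params,
    curve_by_condition: Optional[Mapping[str, UtilityCurve]] = None,
    n_total: int = DEFAULT_N_TOTAL,
    include_actor: bool = True,
) -> float:
    """Negative Bernoulli log-likelihood of a judgment dataset under a model.

    ``params`` is a :class:`~universalize.models.ChoiceParams` for the three
    utility-comparing models, :class:`RuleParams` for the rule model, and
    :class:`NormParams` for the norm model.  Probabilities are clamped to
    ``[1e-12, 1 - 1e-12]`` so the sum is always finite.
    """
    x = _record_features(dataset, model, curve_by_condition, n_total, include_actor)
    y = dataset["judgment"].to_numpy(dtype=float)
    xs, n1, n0 = _aggregate(x, y)
    if model == "rule":
        p = np.full_like(xs, params.p_no_rule)
    elif model == "norm":
        p = 1.0 / (1.0 + np.exp(np.clip(params.tau * (xs - params.theta), -700, 700)))
    else:
        p = 1.0 / (1.0 + np.exp(np.clip(params.tau * xs + params.beta, -700, 700)))
    return float(np.sum(_nll_cells(p, n1, n0)))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _fit_two_param(
    xs, n1, n0, offset_grid, offset_is_theta: bool, config: SearchConfig
) -> tuple[float, float, float, bool]:
    """Grid-then-refine fit of (tau, offset) where the cell probability is
    logistic(-(tau*(x - theta))) for the norm model or logistic(-(tau*x + beta))
    otherwise.  Returns (tau, offset, nll, converged)."""
    taus = config.tau_grid()

    # z[i, j, k]: exponent at (tau_i, offset_j, x_k)
    if offset_is_theta:
        z = taus[:, None, None] * (xs[None, None, :] - offset_grid[None, :, None])
    else:
        z = taus[:, None, None] * xs[None, None, :] + offset_grid[None, :, None]
    p = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
    p = np.clip(p, CLAMP_LO, CLAMP_HI)
    nll = -(n1 * np.log(p) + n0 * np.log1p(-p)).sum(axis=2)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    best = (float(taus[i]), float(offset_grid[j]))
    best_nll = float(nll[i, j])

    if not config.refine:
        return best[0], best[1], best_nll, True

    def objective(v):
        tau, off = v
        if offset_is_theta:
            off = float(np.clip(off, 1e-6, 1.0 - 1e-6))
            zz = tau * (xs - off)
        else:
            zz = tau * xs + off
        pp = 1.0 / (1.0 + np.exp(np.clip(zz, -700, 700)))
        pp = np.clip(pp, CLAMP_LO, CLAMP_HI)
        return float(-(n1 * np.log(pp) + n0 * np.log1p(-pp)).sum())

    res = minimize(objective, np.array(best), method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    refined_nll = float(res.fun)
    converged = refined_nll <= best_nll + config.refine_tol
    if refined_nll <= best_nll:
        tau, off = float(res.x[0]), float(res.x[1])
        if offset_is_theta:
            off = float(np.clip(off, 1e-6, 1.0 - 1e-6))
        return tau, off, refined_nll, converged
    return best[0], best[1], best_nll, converged


def fit_mle(
    dataset: pd.DataFrame,
    model: str,
    curve_by_condition: Optional[Mapping[str, UtilityCurve]] = None,
    search_config: Optional[SearchConfig] = None,
    n_total: int = DEFAULT_N_TOTAL,
    include_actor: bool = True,
    utility_source: str = "idealized",
) -> FitResult:
    """Fit a judgment model by maximum likelihood.

    A single parameter set is fitted jointly to all conditions (records
    weighted equally).  Free parameters: (tau, beta) for universalization /
    outcome / pessimistic, p for rule, (tau, theta) for norm.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    config = search_config or SearchConfig()
    x = _record_features(dataset, model, curve_by_condition, n_total, include_actor)
    y = dataset["judgment"].to_numpy(dtype=float)
    xs, n1, n0 = _aggregate(x, y)
    n_obs = len(dataset)

    if model == "rule":
        # All records are rule-absent here, so the MLE is the clamped mean.
        p_hat = float(np.clip(y.mean(), CLAMP_LO, CLAMP_HI))
        converged = CLAMP_LO < p_hat < CLAMP_HI
        nll = float(np.sum(_nll_cells(np.full_like(xs, p_hat), n1, n0)))
        params = {"p_no_rule": p_hat}
    elif model == "norm":
        tau, theta, nll, converged = _fit_two_param(
            xs, n1, n0, config.theta_grid(), True, config
        )
        params = {"tau": tau, "theta": theta}
    else:
        tau, beta, nll, converged = _fit_two_param(
            xs, n1, n0, config.beta_grid(), False, config
        )
        params = {"tau": tau, "beta": beta}

    lnl = -nll
    return FitResult(
        model=model,
        params=params,
        log_likelihood=lnl,
        aic=aic(lnl, N_PARAMS[model]),
        n_observations=n_obs,
        converged=bool(converged),
        utility_source=utility_source,
    )


# ---------------------------------------------------------------------------
# Utility curves for fitting
# ---------------------------------------------------------------------------

def empirical_utility_from_ratings(
    ratings: pd.DataFrame,
    condition: str,
) -> UtilityCurve:
    """Empirical utility curve for one condition from elicited ratings.

    Ratings encode ``U(n) - U(0)``, so the curve is anchored at
    ``U(0) = 0``; the value at each probed ``n`` is the mean rating there,
    and unprobed interior values are linearly interpolated between probed
    neighbours.  The curve's support ends at the largest probed ``n``
    (no extrapolation).
    """
    sub = ratings[ratings["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(f"no ratings for condition {condition!r}")
    means = sub.groupby("n_actors")["rating"].mean()
    probes = np.asarray(sorted(means.index), dtype=int)
    if probes.min() < 0:
        raise ValueError("probed n must be non-negative")
    xp = probes.astype(float)
    fp = means.loc[probes].to_numpy(dtype=float)
    if probes.min() > 0:  # status quo anchor
        xp = np.concatenate([[0.0], xp])
        fp = np.concatenate([[0.0], fp])
    n_max = int(probes.max())
    values = np.interp(np.arange(n_max + 1), xp, fp)
    return UtilityCurve(n_max, tuple(values), kind_label="empirical")


def make_idealized_fit_curve(condition: str, n_total: int = DEFAULT_N_TOTAL) -> UtilityCurve:
    """Two-valued idealized step curve used as the fitting baseline: 0 below
    the condition's collapse point and 1 at or above it.

    The essential feature is that the values are constant on each side of
    the threshold; the coding direction is immaterial because the
    temperature's sign can flip jointly with a 0/1 recoding.
    """
    harm_onset, collapse_point = condition_bounds(condition)
    if collapse_point > n_total:
        raise ValueError(f"collapse_point={collapse_point} exceeds n_total={n_total}")
    values = (np.arange(n_total + 1) >= collapse_point).astype(float)
    return UtilityCurve(n_total, tuple(values), kind_label="custom")


# ---------------------------------------------------------------------------
# Response-profile classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSummary:
    """Per-participant response-profile labels and their proportions.

    ``proportions`` is computed over complete participants only and sums to
    1; participants with incomplete designs are listed separately.
    """

    labels: dict
    proportions: dict
    incomplete: tuple

    def counts(self) -> dict:
        out = {lab: 0 for lab in PROFILE_LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out


def classify_profiles(
    dataset: pd.DataFrame,
    expected_grid: Optional[Mapping[str, Sequence[int]]] = None,
) -> ProfileSummary:
    """Classify each participant as uniform-acceptable (all 1), uniform-
    unacceptable (all 0), or non-uniform.

    A participant is *complete* when they answered every interested-party
    level of their condition's grid (by default, every level observed for
    that condition in the dataset); incomplete participants are reported
    separately and excluded from the proportions.
    """
    if expected_grid is None:
        expected_grid = {
            cond: set(sub["n_interested"]) for cond, sub in dataset.groupby("condition")
        }
    else:
        expected_grid = {c: set(g) for c, g in expected_grid.items()}

    labels: dict = {}
    incomplete: list = []
    for pid, sub in dataset.groupby("participant_id"):
        cond = sub["condition"].iloc[0]
        seen = set(sub["n_interested"])
        if seen != expected_grid.get(cond, seen):
            incomplete.append(pid)
            continue
        j = sub["judgment"].to_numpy()
        if np.all(j == 1):
            labels[pid] = "uniform_acceptable"
        elif np.all(j == 0):
            labels[pid] = "uniform_unacceptable"
        else:
            labels[pid] = "non_uniform"

    n = len(labels)
    proportions = {
        lab: (sum(1 for v in labels.values() if v == lab) / n if n else 0.0)
        for lab in PROFILE_LABELS
    }
    return ProfileSummary(labels=labels, proportions=proportions, incomplete=tuple(incomplete))


def filter_non_uniform(
    dataset: pd.DataFrame,
    expected_grid: Optional[Mapping[str, Sequence[int]]] = None,
) -> pd.DataFrame:
    """Keep only records of participants with a non-uniform judgment profile
    (the subset whose data can identify the choice parameters)."""
    summary = classify_profiles(dataset, expected_grid)
    keep = {pid for pid, lab in summary.labels.items() if lab == "non_uniform"}
    return dataset[dataset["participant_id"].isin(keep)].reset_index(drop=True)
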