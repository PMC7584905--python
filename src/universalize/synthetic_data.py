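"""Synthetic judgment and utility-rating datasets.

Emulates the repeated-measures factorial design used to probe threshold
dilemmas: each simulated participant is assigned one harm-threshold condition
(e.g. ``4_7`` or ``10_13`` out of a 20-person group) and judges the
acceptability of one actor's action at every interested-party count in the
design grid ``{0, 2, 7, 8, 13, 19}``.  The participant population is a
mixture of three response strategies:

- *uniform acceptable* — answers "acceptable" at every grid point;
- *uniform unacceptable* — answers "unacceptable" everywhere;
- *universalizer* — draws each judgment from the universalization model's
  Bernoulli probability under the condition's idealized utility curve.

The default mixture (0.55 / 0.18 / 0.27) and the default universalizer
parameters (tau=6, beta=-3, i.e. ~95% acceptance below the harm threshold
and ~5% above it) reproduce the observed partition of adult participants
into uniform and step-like responders.

Utility ratings emulate the elicitation of ``U(n) - U(0)`` on a -50..50
scale at ``n in {1, 3, 8, 9, 14, 20}``: a mean step-like curve that is
slightly positive with a shallow negative slope below the threshold and
strongly negative with a shallow slope above it, plus truncated Gaussian
noise.

Reproducibility: every participant draws from an independent stream derived
from the master seed via ``numpy.random.SeedSequence(seed, spawn_key=...)``,
so datasets are stable under changes of ``n_participants`` up to the shared
prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .models import ChoiceParams, p_universalization
from .scenarios import (
    ThresholdScenario,
    UtilityCurve,
    condition_bounds,
    make_idealized_threshold_curve,
)

__all__ = [
    "RATING_MIN",
    "RATING_MAX",
    "DEFAULT_NI_GRID",
    "DEFAULT_RATING_GRID",
    "DEFAULT_CONDITIONS",
    "DEFAULT_N_TOTAL",
    "DEFAULT_UNIVERSALIZER_PARAMS",
    "DEFAULT_MIXTURE",
    "StrategyMixture",
    "sloped_plateau_mean_curve",
    "simulate_judgments",
    "simulate_utility_ratings",
    "write_judgments",
    "read_judgments",
    "write_ratings",
    "read_ratings",
]

RATING_MIN = -50.0
RATING_MAX = 50.0

DEFAULT_N_TOTAL = 20
DEFAULT_NI_GRID = (0, 2, 7, 8, 13, 19)
DEFAULT_RATING_GRID = (1, 3, 8, 9, 14, 20)
DEFAULT_CONDITIONS = ("4_7", "10_13")

JUDGMENT_COLUMNS = ["participant_id", "condition", "n_interested", "judgment"]
RATING_COLUMNS = ["participant_id", "condition", "n_actors", "rating"]

_STRATEGIES = ("uniform_acceptable", "uniform_unacceptable", "universalizer")

DEFAULT_UNIVERSALIZER_PARAMS = ChoiceParams(tau=6.0, beta=-3.0)


@dataclass(frozen=True)
class StrategyMixture:
    """Population mixture over the three response strategies."""

    frac_uniform_acceptable: float
    frac_uniform_unacceptable: float
    frac_universalizer: float
    universalizer_params: ChoiceParams = DEFAULT_UNIVERSALIZER_PARAMS

    def __post_init__(self) -> None:
        fracs = (
            self.frac_uniform_acceptable,
            self.frac_uniform_unacceptable,
            self.frac_universalizer,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError(f"mixture fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions must sum to 1, got {sum(fracs)}")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (
            self.frac_uniform_acceptable,
            self.frac_uniform_unacceptable,
            self.frac_universalizer,
        )


DEFAULT_MIXTURE = StrategyMixture(0.55, 0.18, 0.27)


def _participant_rng(seed: int, namespace: int, index: int) -> np.random.Generator:
    # One independent, prefix-stable stream per participant.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(namespace, index)))


def sloped_plateau_mean_curve(
    condition: str,
    n_total: int = DEFAULT_N_TOTAL,
    pre_start: float = 8.0,
    pre_end: float = 4.0,
    post_start: float = -30.0,
    post_end: float = -40.0,
) -> UtilityCurve:
    """Mean elicited-utility curve on the -50..50 scale: slightly positive
    with a shallow negative slope below the harm threshold, strongly
    negative with a shallow slope above it, anchored at ``U(0) = 0``.

    The shallow slopes on both plateaus emulate the empirically observed
    deviation from the idealized flat-plateau curve.
    """
    harm_onset, collapse_point = condition_bounds(condition)
    if collapse_point > n_total:
        raise ValueError(f"collapse_point={collapse_point} exceeds n_total={n_total}")
    values = np.empty(n_total + 1)
    values[0] = 0.0
    pre = np.linspace(pre_start, pre_end, max(harm_onset, 1))
    values[1 : harm_onset + 1] = pre[: harm_onset]
    mid = np.linspace(pre_end, post_start, collapse_point - harm_onset + 1)
    values[harm_onset : collapse_point + 1] = mid
    post = np.linspace(post_start, post_end, n_total - collapse_point + 1)
    values[collapse_point:] = post
    values[0] = 0.0  # ratings are relative to the status quo
    return UtilityCurve(n_total, tuple(values), kind_label="custom")


# ---------------------------------------------------------------------------
# Judgment simulation
# ---------------------------------------------------------------------------

def simulate_judgments(
    n_participants: int,
    mixture: StrategyMixture = DEFAULT_MIXTURE,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    ni_grid: Sequence[int] = DEFAULT_NI_GRID,
    seed: int = 0,
    n_total: int = DEFAULT_N_TOTAL,
    curve_by_condition: Optional[Mapping[str, UtilityCurve]] = None,
    include_actor: bool = True,
    return_strategies: bool = False,
):
    """Simulate a long-format binary judgment dataset.

    Each participant is assigned one strategy by the mixture proportions and
    one condition uniformly at random, then judges every grid point of that
    condition.  Universalizers draw Bernoulli judgments from the
    universalization probability under ``curve_by_condition`` (default: the
    condition's idealized 1/0 threshold curve).

    With ``return_strategies=True`` also returns the per-participant strategy
    assignment as a Series indexed by participant id.
    """
    if n_participants <= 0:
        raise ValueError(f"n_participants must be positive, got {n_participants}")
    ni_grid = [int(n) for n in ni_grid]
    conditions = list(conditions)
    if not ni_grid or not conditions:
        raise ValueError("ni_grid and conditions must be non-empty")

    if curve_by_condition is None:
        curve_by_condition = {
            c: make_idealized_threshold_curve(n_total, *condition_bounds(c))
            for c in conditions
        }
    # Precompute the universalizer probability at each (condition, ni) cell.
    p_univ: dict[tuple[str, int], float] = {}
    for c in conditions:
        curve = curve_by_condition[c]
        harm_onset, collapse_point = condition_bounds(c)
        for ni in ni_grid:
            scen = ThresholdScenario(
                n_total=n_total,
                n_interested=ni,
                curve=curve,
                harm_onset=harm_onset,
                collapse_point=collapse_point,
            )
            p_univ[(c, ni)] = p_universalization(
                scen, mixture.universalizer_params, include_actor=include_actor
            )

    cum = np.cumsum(mixture.fractions)
    rows = []
    strategies = {}
    width = max(4, len(str(n_participants - 1)))
    for i in range(n_participants):
        rng = _participant_rng(seed, 0, i)
        pid = f"P{i:0{width}d}"
        strategy = _STRATEGIES[int(np.searchsorted(cum, rng.random(), side="right"))]
        condition = conditions[int(rng.integers(len(conditions)))]
        strategies[pid] = strategy
        for ni in ni_grid:
            if strategy == "uniform_acceptable":
                judgment = 1
            elif strategy == "uniform_unacceptable":
                judgment = 0
            else:
                judgment = int(rng.random() < p_univ[(condition, ni)])
            rows.append((pid, condition, ni, judgment))

    df = pd.DataFrame(rows, columns=JUDGMENT_COLUMNS)
    if return_strategies:
        return df, pd.Series(strategies, name="strategy")
    return df


# ---------------------------------------------------------------------------
# Utility-rating simulation
# ---------------------------------------------------------------------------

def simulate_utility_ratings(
    n_participants: int,
    condition: str,
    mean_curve: Optional[UtilityCurve] = None,
    noise_sd: float = 10.0,
    n_grid: Sequence[int] = DEFAULT_RATING_GRID,
    seed: int = 0,
    n_total: int = DEFAULT_N_TOTAL,
) -> pd.DataFrame:
    """Simulate ratings of ``U(n) - U(0)`` on the -50..50 scale.

    Each rating is the mean curve's value plus Gaussian noise truncated to
    the scale bounds (with ``noise_sd=0`` the mean itself, clipped to the
    scale).
    """
    if n_participants <= 0:
        raise ValueError(f"n_participants must be positive, got {n_participants}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if mean_curve is None:
        mean_curve = sloped_plateau_mean_curve(condition, n_total=n_total)
    n_grid = [int(n) for n in n_grid]
    if any(n < 0 or n > mean_curve.n_max for n in n_grid):
        raise ValueError(
            f"grid values must lie within the curve support [0, {mean_curve.n_max}]"
        )

    means = np.array([mean_curve(n) for n in n_grid])
    rows = []
    width = max(4, len(str(n_participants - 1)))
    for i in range(n_participants):
        rng = _participant_rng(seed, 1, i)
        pid = f"R{i:0{width}d}"
        if noise_sd == 0:
            ratings = np.clip(means, RATING_MIN, RATING_MAX)
        else:
            a = (RATING_MIN - means) / noise_sd
            b = (RATING_MAX - means) / noise_sd
            ratings = truncnorm.rvs(a, b, loc=means, scale=noise_sd, random_state=rng)
        for n, r in zip(n_grid, ratings):
            rows.append((pid, condition, n, float(r)))
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if list(df.columns) != columns:
        raise ValueError(f"expected columns {columns}, got {list(df.columns)}")
    df.to_csv(path, index=False, lineterminator="\n")


def write_judgments(df: pd.DataFrame, path: str | Path) -> None:
    """Write a judgment dataset (header ``participant_id,condition,n_interested,judgment``)."""
    _write_csv(df, path, JUDGMENT_COLUMNS)


def read_judgments(path: str | Path) -> pd.DataFrame:
    """Read and validate a judgment dataset; rejects malformed rows by number."""
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str})
    if list(df.columns) != JUDGMENT_COLUMNS:
        raise ValueError(f"expected header {','.join(JUDGMENT_COLUMNS)}, got {list(df.columns)}")
    bad = df.index[~df["judgment"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"judgment must be 0 or 1; first offending row {int(bad[0]) + 1}")
    bad = df.index[df["n_interested"] < 0]
    if len(bad):
        raise ValueError(f"n_interested must be non-negative; first offending row {int(bad[0]) + 1}")
    return df


def write_ratings(df: pd.DataFrame, path: str | Path) -> None:
    """Write a rating dataset (header ``participant_id,condition,n_actors,rating``)."""
    bad = df.index[(df["rating"] < RATING_MIN) | (df["rating"] > RATING_MAX)]
    if len(bad):
        raise ValueError(f"rating outside [-50, 50]; first offending row {int(bad[0]) + 1}")
    _write_csv(df, path, RATING_COLUMNS)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read and validate a rating dataset; rejects out-of-scale ratings by row."""
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str})
    if list(df.columns) != RATING_COLUMNS:
        raise ValueError(f"expected header {','.join(RATING_COLUMNS)}, got {list(df.columns)}")
    bad = df.index[(df["rating"] < RATING_MIN) | (df["rating"] > RATING_MAX)]
    if len(bad):
        raise ValueError(f"rating outside [-50, 50]; first offending row {int(bad[0]) + 1}")
    return df
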