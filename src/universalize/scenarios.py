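"""Utility curves and scenario skeletons for collective-action dilemmas.

A *threshold problem* is a social dilemma in which the aggregate utility
``U(n)`` of ``n`` people taking some action is flat while few act, collapses
within a critical interior range of actor counts (the *harm threshold*), and
is flat again beyond it — e.g. up to 4 vacationers may fish with a new hook
with no effect on the fish population, but once 7 use it the population goes
extinct.  This module builds the tabulated utility curves for the three
canonical dilemma families (threshold, aggregation, coordination), the
scenario records that the judgment models consume, and a classifier that
recovers the dilemma family from a curve's shape.

Utility is dimensionless and defined only on integer actor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UtilityCurve",
    "ThresholdScenario",
    "DualRoleScenario",
    "make_idealized_threshold_curve",
    "make_aggregation_curve",
    "make_coordination_curve",
    "classify_dilemma",
    "condition_bounds",
    "condition_label",
]

#: Dilemma-class labels returned by :func:`classify_dilemma`.
DILEMMA_CLASSES = ("threshold", "aggregation", "coordination", "other")

#: Recognised curve tags.
KIND_LABELS = ("idealized_threshold", "empirical", "aggregation", "coordination", "custom")


def condition_bounds(label: str) -> tuple[int, int]:
    """Parse a harm-threshold condition label like ``"4_7"`` into
    ``(harm_onset, collapse_point)``.

    ``harm_onset`` is the largest actor count with no harm; ``collapse_point``
    is the smallest count with full collapse.
    """
    try:
        lo, hi = label.split("_")
        harm_onset, collapse_point = int(lo), int(hi)
    except (ValueError, AttributeError) as exc:
        raise ValueError(
            f"condition label {label!r} is not of the form '<harm>_<collapse>'"
        ) from exc
    if not harm_onset < collapse_point:
        raise ValueError(
            f"condition {label!r}: harm_onset must be < collapse_point"
        )
    return harm_onset, collapse_point


def condition_label(harm_onset: int, collapse_point: int) -> str:
    """Inverse of :func:`condition_bounds`."""
    return f"{harm_onset}_{collapse_point}"


@dataclass(frozen=True)
class UtilityCurve:
    """Tabulated aggregate utility ``U(n)`` for ``n = 0 .. n_max`` actors.

    Evaluation at an integer ``n`` returns ``values[n]`` exactly; there is no
    interpolation between tabulated points, because the number of actors is a
    count.  Larger values mean a better collective outcome.
    """

    n_max: int
    values: tuple[float, ...]
    kind_label: Optional[str] = None

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if self.n_max < 0:
            raise ValueError(f"n_max must be non-negative, got {self.n_max}")
        if len(vals) != self.n_max + 1:
            raise ValueError(
                f"values has length {len(vals)}, expected n_max + 1 = {self.n_max + 1}"
            )
        if not all(np.isfinite(vals)):
            raise ValueError("all utility values must be finite")
        if self.kind_label is not None and self.kind_label not in KIND_LABELS:
            raise ValueError(
                f"kind_label {self.kind_label!r} not in {KIND_LABELS}"
            )

    def __call__(self, n: int) -> float:
        n = int(n)
        if not 0 <= n <= self.n_max:
            raise ValueError(f"n={n} outside curve support [0, {self.n_max}]")
        return self.values[n]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    # -- CSV round trip (header `n,utility`, one row per integer n) ----------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"n": np.arange(self.n_max + 1), "utility": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, kind_label: Optional[str] = None) -> "UtilityCurve":
        df = pd.read_csv(path)
        if list(df.columns) != ["n", "utility"]:
            raise ValueError(f"expected header 'n,utility', got {list(df.columns)}")
        if not np.array_equal(df["n"].to_numpy(), np.arange(len(df))):
            raise ValueError("column n must enumerate 0..n_max with no gaps")
        return cls(n_max=len(df) - 1, values=tuple(df["utility"]), kind_label=kind_label)


@dataclass(frozen=True)
class ThresholdScenario:
    """Formal skeleton of a collective-action vignette.

    Fields
    ------
    n_total:
        Group size (e.g. 20 vacationers).
    harm_onset, collapse_point:
        Bounds of the harm threshold: the largest actor count with no harm
        and the smallest with full collapse.  ``None`` when the scenario has
        no threshold (a flat or otherwise unstructured curve).
    n_interested:
        Number of interested parties ``n_i`` — agents who would act if they
        felt morally at liberty to, whether or not they actually do.
    n_actual:
        Current actual number of actors ``n_a`` (0 in all the studies here).
    rule_present:
        Whether an explicit rule prohibits the action.
    norm_count:
        Number of parties ``n_p`` exhibiting a prohibitive norm.
    curve:
        The aggregate utility curve ``U(n)`` with ``n_max = n_total``.
    """

    n_total: int
    n_interested: int
    curve: UtilityCurve
    harm_onset: Optional[int] = None
    collapse_point: Optional[int] = None
    n_actual: int = 0
    rule_present: bool = False
    norm_count: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_actual <= self.n_interested <= self.n_total:
            raise ValueError(
                "require 0 <= n_actual <= n_interested <= n_total, got "
                f"n_actual={self.n_actual}, n_interested={self.n_interested}, "
                f"n_total={self.n_total}"
            )
        if (self.harm_onset is None) != (self.collapse_point is None):
            raise ValueError("harm_onset and collapse_point must be given together")
        if self.harm_onset is not None:
            if not 0 <= self.harm_onset < self.collapse_point <= self.n_total:
                raise ValueError(
                    "require 0 <= harm_onset < collapse_point <= n_total, got "
                    f"harm_onset={self.harm_onset}, collapse_point={self.collapse_point}, "
                    f"n_total={self.n_total}"
                )
        if not 0 <= self.norm_count <= self.n_total:
            raise ValueError(
                f"norm_count={self.norm_count} outside [0, n_total={self.n_total}]"
            )
        if self.curve.n_max != self.n_total:
            raise ValueError(
                f"curve n_max={self.curve.n_max} must equal n_total={self.n_total}"
            )

    def with_n_interested(self, n_interested: int) -> "ThresholdScenario":
        return replace(self, n_interested=int(n_interested))


@dataclass(frozen=True)
class DualRoleScenario:
    """A vignette in which the actor's own utility ``U_j`` and the other
    parties' utility ``U_f`` are tracked separately, as functions of the
    number of actors ``n``.

    In the *fisherman* structure the actor shares the collapsing curve; in
    the *tour boat* structure the actor's utility is unaffected by how many
    others act.
    """

    actor_curve: UtilityCurve
    others_curve: UtilityCurve
    n_total: int
    n_interested: int

    def __post_init__(self) -> None:
        if self.actor_curve.n_max != self.n_total or self.others_curve.n_max != self.n_total:
            raise ValueError("both curves must share n_max = n_total")
        if not 0 <= self.n_interested <= self.n_total:
            raise ValueError(
                f"n_interested={self.n_interested} outside [0, n_total={self.n_total}]"
            )


# ---------------------------------------------------------------------------
# Curve constructors (the three canonical dilemma families)
# ---------------------------------------------------------------------------

def make_idealized_threshold_curve(
    n_total: int,
    harm_onset: int,
    collapse_point: int,
    u_high: float = 1.0,
    u_low: float = 0.0,
) -> UtilityCurve:
    """Idealized threshold curve: high plateau up to ``harm_onset``, low
    plateau from ``collapse_point``, linear descent in between.

    The plateaus are what the vignettes pin down ("up to four people ... no
    effect"; "once seven people ... extinct"); the within-threshold shape is
    underdetermined, and a linear descent is used for determinism.
    """
    if not 0 <= harm_onset:
        raise ValueError(f"harm_onset={harm_onset} must be non-negative")
    if not harm_onset < collapse_point:
        raise ValueError(
            f"harm_onset={harm_onset} must be < collapse_point={collapse_point}"
        )
    if not collapse_point <= n_total:
        raise ValueError(
            f"collapse_point={collapse_point} must be <= n_total={n_total}"
        )
    if not u_high > u_low:
        raise ValueError(f"u_high={u_high} must exceed u_low={u_low}")
    n = np.arange(n_total + 1)
    frac = np.clip((n - harm_onset) / (collapse_point - harm_onset), 0.0, 1.0)
    values = u_high + frac * (u_low - u_high)
    return UtilityCurve(n_total, tuple(values), kind_label="idealized_threshold")


def make_aggregation_curve(n_total: int, per_act_loss: float) -> UtilityCurve:
    """Aggregation dilemma: each act adds the same negative utility, so
    ``U(n) = -n * per_act_loss`` (strictly decreasing, e.g. littering)."""
    if not per_act_loss > 0:
        raise ValueError(f"per_act_loss={per_act_loss} must be positive")
    values = -np.arange(n_total + 1, dtype=float) * per_act_loss
    return UtilityCurve(n_total, tuple(values), kind_label="aggregation")


def make_coordination_curve(n_total: int, u_uniform: float, u_mixed: float) -> UtilityCurve:
    """Coordination dilemma: high utility when everyone acts alike (``n=0``
    or ``n=n_total``), low for any mixed profile (e.g. which side to drive on)."""
    if not u_uniform > u_mixed:
        raise ValueError(f"u_uniform={u_uniform} must exceed u_mixed={u_mixed}")
    values = np.full(n_total + 1, float(u_mixed))
    values[0] = values[-1] = u_uniform
    return UtilityCurve(n_total, tuple(values), kind_label="coordination")


# ---------------------------------------------------------------------------
# Shape classification
# ---------------------------------------------------------------------------

def classify_dilemma(curve: UtilityCurve, tol: float = 1e-9) -> str:
    """Classify a curve as ``threshold``, ``aggregation``, ``coordination``
    or ``other`` from its shape alone.

    - *aggregation*: successive differences all negative and equal within tol;
    - *coordination*: both endpoints exceed every interior value by > tol;
    - *threshold*: all decreases (beyond tol) lie in one contiguous interior
      run with flat plateaus (within tol) on both sides.

    Checked in that order; the first match wins (this breaks degenerate ties
    deterministically).
    """
    if tol < 0:
        raise ValueError(f"tol={tol} must be non-negative")
    vals = curve.as_array()
    if len(vals) < 3:
        raise ValueError("classification undefined for curves shorter than 3 points")
    diffs = np.diff(vals)

    # aggregation: constant strictly negative slope
    if np.all(diffs < -tol) and np.ptp(diffs) <= tol:
        return "aggregation"

    # coordination: uniform endpoints strictly above every interior value
    interior = vals[1:-1]
    if (
        abs(vals[0] - vals[-1]) <= tol
        and np.all(vals[0] - interior > tol)
        and np.all(vals[-1] - interior > tol)
    ):
        return "coordination"

    # threshold: one contiguous interior descending run, flat elsewhere
    decreasing = diffs < -tol
    flat = np.abs(diffs) <= tol
    if np.any(decreasing) and np.all(decreasing | flat):
        idx = np.nonzero(decreasing)[0]
        first, last = idx[0], idx[-1]
        contiguous = np.all(decreasing[first : last + 1])
        has_plateaus = first > 0 and last < len(diffs) - 1
        if contiguous and has_plateaus:
            return "threshold"

    return "other"
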