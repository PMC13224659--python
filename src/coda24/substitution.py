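"""Compositional isotemporal substitution: what-if time reallocations.

Given a fitted compositional regression and a base composition (the cohort's
closed geometric-mean day), the predicted change in an outcome when `m`
minutes move from one behaviour to another — the day total held fixed — is

    delta = beta_ilr' * d,     d = ilr(base with m min moved) - ilr(base)

because the intercept and covariate terms cancel in the difference of two
predictions that share everything but the composition. The delta-method
variance is d' Cov(beta_ilr) d, giving a Student-t confidence interval with
the model's residual degrees of freedom. Reallocations that would drive a
part to zero or below are infeasible and reported as such rather than
computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import Composition, geometric_mean_composition, ilr_transform
from .models import CompositionalFit
from .preprocessing import ChildRecord

__all__ = [
    "Reallocation",
    "SubstitutionEstimate",
    "InfeasibleReallocation",
    "reference_composition",
    "apply_reallocation",
    "estimate_substitution",
    "substitution_table",
    "reallocation_curve",
    "substitution_frame",
]


class InfeasibleReallocation(ValueError):
    """The requested reallocation would drive a behaviour to zero or below."""


@dataclass(frozen=True)
class Reallocation:
    """Move `minutes` from one behaviour to another, total unchanged."""

    from_behaviour: str
    to_behaviour: str
    minutes: float

    def __post_init__(self) -> None:
        if self.from_behaviour == self.to_behaviour:
            raise ValueError("from and to behaviours must differ")
        if self.minutes <= 0:
            raise ValueError(f"minutes must be positive, got {self.minutes}")


@dataclass(frozen=True)
class SubstitutionEstimate:
    reallocation: Reallocation
    delta: float
    ci_low: float
    ci_high: float
    significant: bool


def reference_composition(records: Sequence[ChildRecord]) -> Composition:
    """Cohort compositional centre: per-part geometric means closed to 1440."""
    if not records:
        raise ValueError("empty cohort")
    return geometric_mean_composition([r.composition for r in records])


def apply_reallocation(base: Composition, r: Reallocation) -> Composition:
    """Shift minutes between two parts of a composition."""
    if r.from_behaviour not in base.parts or r.to_behaviour not in base.parts:
        raise KeyError(f"unknown behaviour in reallocation {r}")
    new_from = base[r.from_behaviour] - r.minutes
    if new_from <= 0:
        raise InfeasibleReallocation(
            f"moving {r.minutes} min from {r.from_behaviour} "
            f"({base[r.from_behaviour]:.1f} min available) empties the part"
        )
    return base.replace(**{
        r.from_behaviour: new_from,
        r.to_behaviour: base[r.to_behaviour] + r.minutes,
    })


def estimate_substitution(
    fit: CompositionalFit,
    base: Composition,
    r: Reallocation,
    alpha: float = 0.05,
) -> SubstitutionEstimate:
    """Predicted outcome change with delta-method CI for one reallocation."""
    if base.names != tuple(fit.spec.behaviours):
        raise ValueError("base composition and fit use different behaviour sets")
    moved = apply_reallocation(base, r)
    d = ilr_transform(moved, fit.basis).coords - ilr_transform(base, fit.basis).coords
    delta = float(fit.beta_ilr @ d)
    var = float(d @ fit.cov_ilr @ d)
    tq = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    half = tq * np.sqrt(max(var, 0.0))
    lo, hi = delta - half, delta + half
    return SubstitutionEstimate(
        reallocation=r, delta=delta, ci_low=lo, ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
    )


def substitution_table(
    fit: CompositionalFit,
    base: Composition,
    minutes_list: Sequence[float] = (10.0, 20.0, 30.0),
    alpha: float = 0.05,
) -> list[SubstitutionEstimate | tuple[Reallocation, str]]:
    """All ordered one-to-one reallocations at each minutes value.

    Yields D*(D-1) estimates per minutes value; infeasible cells are
    returned as (reallocation, reason) tuples instead of estimates.
    """
    out: list[SubstitutionEstimate | tuple[Reallocation, str]] = []
    names = base.names
    for m in minutes_list:
        for src in names:
            for dst in names:
                if src == dst:
                    continue
                r = Reallocation(src, dst, m)
                try:
                    out.append(estimate_substitution(fit, base, r, alpha))
                except InfeasibleReallocation as e:
                    out.append((r, str(e)))
    return out


def reallocation_curve(
    fit: CompositionalFit,
    base: Composition,
    from_behaviour: str,
    to_behaviour: str,
    max_minutes: float = 30.0,
    step: float = 1.0,
    alpha: float = 0.05,
) -> list[SubstitutionEstimate]:
    """Delta and CI band on a minutes grid 1*step .. max_minutes.

    The grid is truncated at the first infeasible point (the source
    behaviour running out of minutes); truncation is reported by the
    shorter returned series.
    """
    out: list[SubstitutionEstimate] = []
    grid = np.arange(step, max_minutes + step / 2, step)
    for m in grid:
        r = Reallocation(from_behaviour, to_behaviour, float(m))
        try:
            out.append(estimate_substitution(fit, base, r, alpha))
        except InfeasibleReallocation:
            break
    return out


def substitution_frame(
    estimates_by_outcome: dict[str, Sequence[SubstitutionEstimate | tuple]],
) -> pd.DataFrame:
    """Flatten substitution estimates to a tidy DataFrame for CSV export."""
    rows = []
    for outcome, ests in estimates_by_outcome.items():
        for e in ests:
            if isinstance(e, SubstitutionEstimate):
                rows.append({
                    "outcome": outcome,
                    "from": e.reallocation.from_behaviour,
                    "to": e.reallocation.to_behaviour,
                    "minutes": e.reallocation.minutes,
                    "delta": e.delta, "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "significant": e.significant, "feasible": True,
                })
            else:
                r, _reason = e
                rows.append({
                    "outcome": outcome, "from": r.from_behaviour,
                    "to": r.to_behaviour, "minutes": r.minutes,
                    "delta": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "significant": False, "feasible": False,
                })
    return pd.DataFrame(rows)
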