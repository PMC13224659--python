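"""Compositional primitives: closure, zero handling and pivot (ilr) coordinates.

A day of a preschool child's life is treated as a *composition*: a vector of
strictly positive parts (minutes spent in each movement behaviour) that
carries only relative information and is closed to a fixed total, here
1440 min. Because the parts are constrained to a simplex, ordinary linear
models cannot be applied to the raw minutes; instead the composition is
mapped to D-1 unconstrained real coordinates with an isometric log-ratio
(ilr) transform. The *pivot* variant of the ilr places one "dominant"
behaviour first, so that the first coordinate

    ilr1 = sqrt((D-1)/D) * ln( x_dom / g(remaining parts) )

contrasts that behaviour against the geometric mean g(.) of all the others.
A positive ilr1 means relatively more of the dominant behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DAY_MINUTES",
    "Composition",
    "PivotBasis",
    "IlrVector",
    "close",
    "zero_replace",
    "geometric_mean_composition",
    "pivot_basis",
    "ilr_transform",
    "ilr_inverse",
]

DAY_MINUTES = 1440.0

#: 4-part whole-day behaviour set used in the primary analysis.
BEHAVIOURS_4 = ("sleep", "sedentary", "light_games", "energetic")
#: 5-part set with sedentary time disaggregated into screen and quiet play.
BEHAVIOURS_5 = ("sleep", "screen", "quiet_play", "light_games", "energetic")


class CompositionError(ValueError):
    """Raised for invalid compositional input (zero/negative parts, etc.)."""


@dataclass(frozen=True)
class Composition:
    """A closed composition of named behaviour minutes.

    Parameters
    ----------
    parts
        Ordered mapping behaviour name -> minutes; all strictly positive.
    total
        The closure constant in minutes (default the 1440-min day).
    """

    parts: dict[str, float]
    total: float = DAY_MINUTES

    def __post_init__(self) -> None:
        if not self.parts:
            raise CompositionError("composition needs at least one part")
        object.__setattr__(self, "parts",
                           {k: float(v) for k, v in self.parts.items()})
        object.__setattr__(self, "total", float(self.total))
        if not 2 <= len(self.parts) <= 8:
            raise CompositionError(
                f"behaviour set size {len(self.parts)} outside supported range 2..8"
            )
        for name, v in self.parts.items():
            if not np.isfinite(v) or v <= 0:
                raise CompositionError(f"part {name!r} must be strictly positive, got {v}")
        s = sum(self.parts.values())
        if abs(s - self.total) > 1e-9 * max(self.total, 1.0):
            raise CompositionError(
                f"parts sum to {s}, not the declared total {self.total}; close() first"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.parts)

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.parts.values()), dtype=float)

    @property
    def proportions(self) -> np.ndarray:
        return self.values / self.total

    def __getitem__(self, name: str) -> float:
        return self.parts[name]

    def replace(self, **minutes: float) -> "Composition":
        """Return a copy with the given parts set to new minute values."""
        new = dict(self.parts)
        for k, v in minutes.items():
            if k not in new:
                raise KeyError(k)
            new[k] = v
        return Composition(new, self.total)


def close(parts: Mapping[str, float], total: float = DAY_MINUTES) -> Composition:
    """Rescale positive parts to sum to `total` without changing their ratios."""
    if total <= 0:
        raise CompositionError(f"total must be positive, got {total}")
    for name, v in parts.items():
        if not np.isfinite(v) or v <= 0:
            raise CompositionError(f"part {name!r} must be strictly positive, got {v}")
    s = sum(parts.values())
    scale = total / s
    return Composition({k: v * scale for k, v in parts.items()}, total)


def zero_replace(
    parts: Mapping[str, float], replacement: float = 1.0
) -> tuple[dict[str, float], int]:
    """Replace zero parts with a small positive value so log-ratios are defined.

    Returns the amended mapping and the number of replacements made. Values
    are replaced in place of the report, before any proportional splitting,
    so closed totals downstream are unaffected.
    """
    if replacement <= 0:
        raise CompositionError(f"replacement must be positive, got {replacement}")
    out: dict[str, float] = {}
    n_replaced = 0
    for name, v in parts.items():
        if v < 0:
            raise CompositionError(f"part {name!r} is negative: {v}")
        if v == 0:
            out[name] = replacement
            n_replaced += 1
        else:
            out[name] = float(v)
    return out, n_replaced


def geometric_mean_composition(compositions: Sequence[Composition]) -> Composition:
    """Per-part geometric mean across individuals, closed to the common total.

    This is the compositional centre of a cohort — the natural "average day"
    under Aitchison geometry, and the base composition used for time
    reallocation estimates.
    """
    if not compositions:
        raise CompositionError("empty list of compositions")
    names = compositions[0].names
    total = compositions[0].total
    for c in compositions[1:]:
        if c.names != names:
            raise CompositionError("compositions have differing behaviour sets")
        if c.total != total:
            raise CompositionError("compositions have differing totals")
    logs = np.log(np.array([c.values for c in compositions]))
    gm = np.exp(logs.mean(axis=0))
    return close(dict(zip(names, gm)), total)


@dataclass(frozen=True)
class PivotBasis:
    """Orthonormal pivot-coordinate contrast basis for a behaviour set.

    `matrix` is D x (D-1); column j is the j-th sequential binary partition
    contrast after moving the dominant behaviour to the front. Rows follow
    `behaviours` (the declared order), not the pivoted order.
    """

    behaviours: tuple[str, ...]
    dominant: str
    order: tuple[str, ...]  # non-dominant parts in pivot order
    matrix: np.ndarray = field(repr=False)

    @property
    def D(self) -> int:
        return len(self.behaviours)


def pivot_basis(
    behaviours: Sequence[str],
    dominant: str,
    order: Sequence[str] | None = None,
) -> PivotBasis:
    """Build the pivot ilr basis with `dominant` as the first contrast.

    The j-th coordinate (1-based, after moving the dominant part to
    position 1) is

        ilr_j = sqrt((D-j)/(D-j+1)) * ln( x_(j) / (prod_{k>j} x_(k))^(1/(D-j)) )

    so ilr1 contrasts the dominant behaviour against the geometric mean of
    everything else. The ordering of the non-dominant parts affects
    ilr_2..ilr_{D-1} but never ilr1, nor any fitted value of a linear model
    in the full coordinate set (the bases are rotations of one another).
    """
    behaviours = tuple(behaviours)
    if len(set(behaviours)) != len(behaviours):
        raise CompositionError("behaviour names must be unique")
    if dominant not in behaviours:
        raise CompositionError(f"unknown dominant behaviour {dominant!r}")
    if order is None:
        order = tuple(b for b in behaviours if b != dominant)
    else:
        order = tuple(order)
        if sorted(order) != sorted(b for b in behaviours if b != dominant):
            raise CompositionError("order must be a permutation of the non-dominant parts")
    pivot_order = (dominant,) + order
    D = len(behaviours)
    # Contrast matrix in pivot order, then rows permuted back to declared order.
    V = np.zeros((D, D - 1))
    for j in range(1, D):  # coordinate index, 1-based
        r = D - j  # number of parts in the denominator geometric mean
        coef = np.sqrt(r / (r + 1))
        V[j - 1, j - 1] = coef
        V[j:, j - 1] = -coef / r
    perm = [pivot_order.index(b) for b in behaviours]
    matrix = V[perm, :]
    return PivotBasis(behaviours=behaviours, dominant=dominant, order=order, matrix=matrix)


@dataclass(frozen=True)
class IlrVector:
    """(D-1) pivot coordinates of a composition; coords[0] is ilr1."""

    coords: np.ndarray
    basis: PivotBasis

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise CompositionError("ilr coordinates must be finite")


def ilr_transform(c: Composition, b: PivotBasis) -> IlrVector:
    """Map a composition to its pivot coordinates under basis `b`.

    Scale invariant: closing (or any positive rescaling of the parts)
    leaves the coordinates unchanged, because the basis columns sum to zero.
    """
    if c.names != b.behaviours:
        raise CompositionError(
            f"behaviour sets differ: composition {c.names}, basis {b.behaviours}"
        )
    coords = b.matrix.T @ np.log(c.proportions)
    return IlrVector(coords=coords, basis=b)


def ilr_coords(values: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Vectorised ilr for an (n, D) array of positive parts (rows need not be closed)."""
    return np.log(values) @ matrix


def ilr_inverse(v: IlrVector, total: float = DAY_MINUTES) -> Composition:
    """Map pivot coordinates back to a composition closed to `total`."""
    x = np.exp(v.basis.matrix @ np.asarray(v.coords, dtype=float))
    return close(dict(zip(v.basis.behaviours, x)), total)
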