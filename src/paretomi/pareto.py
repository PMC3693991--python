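"""Two-dimensional Pareto order and Pareto-set computation.

The identification layer works with points ``(d, e)`` where ``d`` is the
Tanimoto distance of a database chemical to the query and ``e`` is the
absolute prediction error of one model on that chemical.  Both coordinates
are minimised: a point is *dominated* by another that is coordinate-wise no
larger, and the Pareto set (the minimal front) collects every point that no
other point strictly dominates downward.

Two routes to the front are provided:

* :func:`find_pareto_set` — a divide-and-conquer sweep that repeatedly finds
  one minimal point by random descent and recurses on the two open
  sub-rectangles of points incomparable with it (the region coordinate-wise
  above the minimal point cannot contain front members, and the region below
  it is empty by minimality).
* :func:`brute_force_pareto` — the O(n^2) all-pairs definition, kept as an
  independent oracle for testing.

Comparisons are exact (no floating tolerance): coordinates are short
decimals or ratios of integer bit counts, and a tolerance would silently
merge distinct front points.  Points whose coordinates tie exactly are all
retained on the front, because distinct (compound, model) tags carry
information the selection rules need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, ValidationError

__all__ = [
    "Vector2D",
    "TaggedPoint",
    "Bounds",
    "ParetoSet",
    "dominated_by",
    "strictly_dominated_by",
    "incomparable",
    "initial_pareto_set",
    "find_pareto_point",
    "find_pareto_set",
    "brute_force_pareto",
]


@dataclass(frozen=True, order=True)
class Vector2D:
    """A point in the (distance, error) plane. Both coordinates are minimised."""

    d: float
    e: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d) and math.isfinite(self.e)):
            raise ValidationError(f"non-finite coordinates: ({self.d}, {self.e})")


@dataclass(frozen=True, order=True)
class TaggedPoint:
    """A :class:`Vector2D` tagged with the (compound, model) pair it came from."""

    coords: Vector2D
    compound_id: str
    model_id: str

    @property
    def d(self) -> float:
        return self.coords.d

    @property
    def e(self) -> float:
        return self.coords.e


@dataclass(frozen=True)
class Bounds:
    """Per-coordinate minima over V and maxima over the initial Pareto set."""

    f1_min: float
    f1_max: float
    f2_min: float
    f2_max: float


@dataclass(frozen=True)
class ParetoSet:
    """The minimal front of a point set, with its initial subset and bounds.

    ``initial`` is the union of the minimal points among those achieving the
    per-coordinate minima; in two dimensions it has at most two distinct
    coordinate pairs and every member belongs to the full front.
    """

    points: frozenset[TaggedPoint]
    initial: frozenset[TaggedPoint] = field(default_factory=frozenset)
    bounds: Bounds | None = None

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def distinct_coords(self) -> set[tuple[float, float]]:
        return {(p.d, p.e) for p in self.points}


def _check(v: Vector2D, w: Vector2D) -> None:
    # Vector2D validates on construction; guard against raw tuples sneaking in.
    if not isinstance(v, Vector2D) or not isinstance(w, Vector2D):
        raise ValidationError("dominance comparisons require Vector2D operands")


def dominated_by(v: Vector2D, w: Vector2D) -> bool:
    """True iff v is coordinate-wise no larger than w (v precedes w)."""
    _check(v, w)
    return v.d <= w.d and v.e <= w.e


def strictly_dominated_by(v: Vector2D, w: Vector2D) -> bool:
    """True iff v precedes w and the two points differ."""
    _check(v, w)
    return dominated_by(v, w) and v != w


def incomparable(v: Vector2D, w: Vector2D) -> bool:
    """True iff neither point precedes the other.

    Equivalently, one coordinate is strictly smaller and the other strictly
    larger.
    """
    _check(v, w)
    return not dominated_by(v, w) and not dominated_by(w, v)


def _as_arrays(points: Sequence[TaggedPoint]) -> tuple[np.ndarray, np.ndarray]:
    d = np.fromiter((p.d for p in points), dtype=float, count=len(points))
    e = np.fromiter((p.e for p in points), dtype=float, count=len(points))
    return d, e


def _validate_tags(points: Sequence[TaggedPoint]) -> None:
    tags = {(p.compound_id, p.model_id) for p in points}
    if len(tags) != len(points):
        raise ValidationError("duplicate (compound_id, model_id) tags in vector set")


def initial_pareto_set(
    V: Iterable[TaggedPoint],
) -> tuple[frozenset[TaggedPoint], Bounds]:
    """Initial Pareto set: minimal points among the per-coordinate minimisers.

    For each coordinate j, take the points achieving the minimum of that
    coordinate over V, and among those keep the ones minimal on the *other*
    coordinate; the union over j=1,2 is returned.  Also returns the bounds
    rectangle: per-coordinate minima over V and maxima over the initial set.
    Every returned point belongs to the full Pareto front.
    """
    points = list(V)
    if not points:
        raise EmptyInputError("initial_pareto_set requires a non-empty vector set")
    _validate_tags(points)
    d, e = _as_arrays(points)

    f1_min = float(d.min())
    f2_min = float(e.min())
    # minimal points of V1 = argmin-d set: those with minimal e within it
    in_v1 = d == f1_min
    e_star = e[in_v1].min()
    gamma1 = [p for p, m in zip(points, in_v1) if m and p.e == e_star]
    in_v2 = e == f2_min
    d_star = d[in_v2].min()
    gamma2 = [p for p, m in zip(points, in_v2) if m and p.d == d_star]

    initial = frozenset(gamma1) | frozenset(gamma2)
    f1_max = max(p.d for p in initial)
    f2_max = max(p.e for p in initial)
    return initial, Bounds(f1_min, f1_max, f2_min, f2_max)


def find_pareto_point(
    V: Sequence[TaggedPoint], rng: np.random.Generator | None = None
) -> TaggedPoint:
    """Find one minimal point of V by random descent.

    Starts from a uniformly random candidate and repeatedly moves to the
    first point in scan order that strictly dominates the candidate downward,
    until none exists.  Worst case O(n^2) on a chain; the returned point is
    always a member of the Pareto front (which point may depend on the seed
    when the front has several members).
    """
    points = list(V)
    if not points:
        raise EmptyInputError("find_pareto_point requires a non-empty vector set")
    if rng is None:
        rng = np.random.default_rng()
    d, e = _as_arrays(points)
    idx = int(rng.integers(len(points)))
    while True:
        below = (d <= d[idx]) & (e <= e[idx]) & ((d < d[idx]) | (e < e[idx]))
        if not below.any():
            return points[idx]
        idx = int(np.argmax(below))


def find_pareto_set(
    V: Iterable[TaggedPoint], rng: np.random.Generator | None = None
) -> ParetoSet:
    """Compute the full Pareto front of V.

    Divide-and-conquer with an explicit work stack (the front can be as large
    as V, so recursion depth must not scale with it): find a minimal point
    gamma, emit it together with every point sharing its exact coordinates,
    discard the region dominated by gamma, and continue on the two open
    rectangles strictly left-above and right-below gamma, whose points are
    incomparable with gamma.  The returned set is independent of the seed;
    only the internal search order is randomised.
    """
    points = list(V)
    _validate_tags(points)
    if not points:
        return ParetoSet(frozenset())
    if rng is None:
        rng = np.random.default_rng(0)

    d, e = _as_arrays(points)
    front_idx: list[int] = []
    stack: list[np.ndarray] = [np.arange(len(points))]
    while stack:
        sub = stack.pop()
        if sub.size == 0:
            continue
        ds, es = d[sub], e[sub]
        # random descent to a minimal point of this sub-rectangle
        i = int(rng.integers(sub.size))
        while True:
            below = (ds <= ds[i]) & (es <= es[i]) & ((ds < ds[i]) | (es < es[i]))
            if not below.any():
                break
            i = int(np.argmax(below))
        gd, ge = ds[i], es[i]
        ties = (ds == gd) & (es == ge)
        front_idx.extend(sub[ties])
        stack.append(sub[(ds < gd) & (es > ge)])  # left-above rectangle
        stack.append(sub[(ds > gd) & (es < ge)])  # right-below rectangle
        # everything else is dominated by gamma and is discarded

    front = frozenset(points[i] for i in front_idx)
    initial, bounds = initial_pareto_set(points)
    return ParetoSet(points=front, initial=initial, bounds=bounds)


def brute_force_pareto(V: Iterable[TaggedPoint]) -> frozenset[TaggedPoint]:
    """Reference O(n^2) front: points no other point strictly dominates downward."""
    points = list(V)
    if not points:
        return frozenset()
    d, e = _as_arrays(points)
    # below[i, j] True when point j strictly dominates point i downward
    below = (
        (d[None, :] <= d[:, None])
        & (e[None, :] <= e[:, None])
        & ((d[None, :] < d[:, None]) | (e[None, :] < e[:, None]))
    )
    keep = ~below.any(axis=1)
    return frozenset(p for p, k in zip(points, keep) if k)
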