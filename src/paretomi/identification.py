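"""Model identification for a query chemical.

Given a model table and a query, the chemicals-times-models array is turned
into one joint set of (distance, error) points — distance of each table
chemical to the query by Tanimoto, error of each model on that chemical —
and the Pareto front of that set is the menu of candidate (chemical, model)
pairs: no candidate on the front is both farther and worse than another.

Three selection rules pick one model from the front:

* **APMI** (average Pareto): average each model's errors over the distinct
  chemicals represented in the Pareto neighbourhood (full error rows, not
  only the front coordinates) and take the smallest average.
* **CPMI** (centroid Pareto): take the model tagged to the neighbourhood
  point closest (Euclidean) to the neighbourhood centroid.
* **DMS** (double min score, the nearest-neighbour baseline): take the best
  model of the single most similar chemical.

The *n-Pareto neighbourhood* keeps at most ``n`` front points whose distance
to the query is strictly below a threshold ``tau``; when no front point is
that close, the single nearest front point is used and flagged, so that
every query receives exactly one model (the induced partition of chemical
space is total and disjoint).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, ValidationError
from .models import Chemical, ModelTable
from .pareto import ParetoSet, TaggedPoint, Vector2D, find_pareto_set
from .similarity import tanimoto_distance

__all__ = [
    "NeighbourhoodParams",
    "Neighbourhood",
    "Centroid",
    "IdentificationResult",
    "METHOD_REGISTRY",
    "init_vectors",
    "pareto_neighbourhood",
    "centroid",
    "apmi",
    "cpmi",
    "dms",
    "identify",
]


@dataclass(frozen=True)
class NeighbourhoodParams:
    """Neighbourhood size cap n >= 1 and distance threshold 0 < tau <= 1."""

    n: int = 3
    tau: float = 0.4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"neighbourhood size n must be >= 1, got {self.n}")
        if not (0.0 < self.tau <= 1.0):
            raise ValidationError(f"tau must be in (0, 1], got {self.tau}")


#: The experimentally named method variants and their (method, n, tau) settings.
METHOD_REGISTRY: dict[str, tuple[str, NeighbourhoodParams | None]] = {
    "3-apmi": ("APMI", NeighbourhoodParams(n=3, tau=0.4)),
    "5-apmi": ("APMI", NeighbourhoodParams(n=5, tau=0.7)),
    "3-cpmi": ("CPMI", NeighbourhoodParams(n=3, tau=0.4)),
    "5-cpmi": ("CPMI", NeighbourhoodParams(n=5, tau=0.7)),
    "10-cpmi": ("CPMI", NeighbourhoodParams(n=10, tau=1.0)),
    "dms": ("DMS", None),
}


@dataclass(frozen=True)
class Neighbourhood:
    """At most n front points with d < tau, sorted by ascending distance.

    Ties are broken by ascending error, then compound id, then model id.
    ``fallback_used`` marks the case where no front point lay within tau and
    the nearest one was taken instead.
    """

    points: tuple[TaggedPoint, ...]
    query_id: str
    fallback_used: bool = False

    def chemical_ids(self) -> list[str]:
        """Distinct chemicals represented, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.points:
            seen.setdefault(p.compound_id, None)
        return list(seen)


@dataclass(frozen=True)
class Centroid:
    """Coordinate-wise mean of a neighbourhood's points."""

    d_c: float
    e_c: float


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    method: str
    selected_model: str
    neighbourhood: Neighbourhood | None
    per_model_scores: dict[str, float] = field(default_factory=dict)
    prediction: float | None = None
    tie_break_log: tuple[str, ...] = ()


def init_vectors(
    T: ModelTable,
    q: Chemical,
    distances: Sequence[float] | None = None,
) -> list[TaggedPoint]:
    """Build the joint (distance, error) point set for query q.

    One point per (table chemical, model) pair with a finite prediction;
    a table row whose id equals the query's is excluded (leave-self-out).
    ``distances`` may supply precomputed Tanimoto distances per table row
    (used by the leave-one-out loop to avoid recomputing the full matrix).
    """
    if distances is not None and len(distances) != T.n_chemicals:
        raise ValidationError("precomputed distances length does not match table")
    points: list[TaggedPoint] = []
    for i, chem in enumerate(T.chemicals):
        if chem.id == q.id:
            continue
        d = (
            float(distances[i])
            if distances is not None
            else tanimoto_distance(q.fingerprint, chem.fingerprint)
        )
        for j, name in enumerate(T.model_names):
            e = T.errors[i, j]
            if math.isfinite(e):
                points.append(TaggedPoint(Vector2D(d, float(e)), chem.id, name))
    if not points:
        raise EmptyInputError(
            f"no (chemical, model) vectors available for query {q.id}"
        )
    return points


def _sort_key(p: TaggedPoint) -> tuple[float, float, str, str]:
    return (p.d, p.e, p.compound_id, p.model_id)


def pareto_neighbourhood(
    gamma: ParetoSet, params: NeighbourhoodParams, query_id: str = ""
) -> Neighbourhood:
    """Filter the front to d < tau, sort, truncate to the n nearest.

    Falls back to the single front point of minimal distance when nothing
    passes the threshold, so identification always has a candidate.
    """
    if len(gamma) == 0:
        raise EmptyInputError("empty Pareto set")
    within = sorted((p for p in gamma if p.d < params.tau), key=_sort_key)
    if within:
        return Neighbourhood(tuple(within[: params.n]), query_id, fallback_used=False)
    nearest = min(gamma, key=_sort_key)
    return Neighbourhood((nearest,), query_id, fallback_used=True)


def centroid(nb: Neighbourhood) -> Centroid:
    """Arithmetic mean of the neighbourhood points, coordinate-wise."""
    if not nb.points:
        raise EmptyInputError("empty neighbourhood has no centroid")
    return Centroid(
        d_c=float(np.mean([p.d for p in nb.points])),
        e_c=float(np.mean([p.e for p in nb.points])),
    )


def _front_and_neighbourhood(
    T: ModelTable,
    q: Chemical,
    params: NeighbourhoodParams,
    distances: Sequence[float] | None,
) -> Neighbourhood:
    V = init_vectors(T, q, distances=distances)
    gamma = find_pareto_set(V)
    return pareto_neighbourhood(gamma, params, query_id=q.id)


def apmi(
    T: ModelTable,
    q: Chemical,
    params: NeighbourhoodParams,
    distances: Sequence[float] | None = None,
) -> IdentificationResult:
    """Average-Pareto identification: smallest mean error over neighbours.

    Averages use the full error rows of the distinct chemicals in the
    neighbourhood (a chemical reached through two model tags counts once).
    Equal averages resolve to the model listed first in the collection.
    """
    nb = _front_and_neighbourhood(T, q, params, distances)
    rows = [T.row_index(cid) for cid in nb.chemical_ids()]
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(T.errors[rows, :], axis=0)
    avg = np.where(np.isnan(avg), np.inf, avg)
    best = int(np.argmin(avg))  # argmin takes the first minimum: model order
    log = ()
    if int(np.sum(avg == avg[best])) > 1:
        log = (f"APMI tie on average error {avg[best]:.6g}; model order applied",)
    scores = {name: float(a) for name, a in zip(T.model_names, avg)}
    return IdentificationResult(
        query_id=q.id,
        method="APMI",
        selected_model=T.model_names[best],
        neighbourhood=nb,
        per_model_scores=scores,
        tie_break_log=log,
    )


def cpmi(
    T: ModelTable,
    q: Chemical,
    params: NeighbourhoodParams,
    distances: Sequence[float] | None = None,
) -> IdentificationResult:
    """Centroid-Pareto identification: model of the point nearest the centroid.

    Ties on centroid distance resolve to the point with smaller error, then
    smaller distance, then model order.
    """
    nb = _front_and_neighbourhood(T, q, params, distances)
    c = centroid(nb)
    model_order = {name: k for k, name in enumerate(T.model_names)}

    def dist(p: TaggedPoint) -> float:
        return math.hypot(p.d - c.d_c, p.e - c.e_c)

    ranked = sorted(
        nb.points, key=lambda p: (dist(p), p.e, p.d, model_order[p.model_id])
    )
    best = ranked[0]
    log = ()
    if len(ranked) > 1 and math.isclose(dist(ranked[0]), dist(ranked[1]), abs_tol=0.0):
        log = (
            f"CPMI tie on centroid distance {dist(best):.6g}; "
            "lower-error point selected",
        )
    scores: dict[str, float] = {}
    for p in ranked:  # per-model: closest of its points to the centroid
        scores.setdefault(p.model_id, dist(p))
    return IdentificationResult(
        query_id=q.id,
        method="CPMI",
        selected_model=best.model_id,
        neighbourhood=nb,
        per_model_scores=scores,
        tie_break_log=log,
    )


def dms(
    T: ModelTable,
    q: Chemical,
    distances: Sequence[float] | None = None,
) -> IdentificationResult:
    """Nearest-neighbour baseline: the best model of the most similar chemical.

    Equidistant chemicals resolve to the one with the smaller minimum model
    error, then id order; within the chosen chemical, error ties resolve to
    model order.
    """
    rows = [
        (i, c)
        for i, c in enumerate(T.chemicals)
        if c.id != q.id
    ]
    if not rows:
        raise EmptyInputError(f"no chemicals available for query {q.id}")

    def chem_key(item: tuple[int, Chemical]) -> tuple[float, float, str]:
        i, c = item
        d = (
            float(distances[i])
            if distances is not None
            else tanimoto_distance(q.fingerprint, c.fingerprint)
        )
        best_err = float(np.nanmin(T.errors[i, :]))
        return (d, best_err, c.id)

    i, nearest = min(rows, key=chem_key)
    errs = np.where(np.isfinite(T.errors[i, :]), T.errors[i, :], np.inf)
    best = int(np.argmin(errs))
    d_near = chem_key((i, nearest))[0]
    nb = Neighbourhood(
        (TaggedPoint(Vector2D(d_near, float(errs[best])), nearest.id, T.model_names[best]),),
        query_id=q.id,
    )
    scores = {
        name: float(e) for name, e in zip(T.model_names, T.errors[i, :])
    }
    return IdentificationResult(
        query_id=q.id,
        method="DMS",
        selected_model=T.model_names[best],
        neighbourhood=nb,
        per_model_scores=scores,
    )


def identify(
    T: ModelTable,
    q: Chemical,
    method: str = "APMI",
    params: NeighbourhoodParams | None = None,
    distances: Sequence[float] | None = None,
    attach_prediction: bool = True,
) -> IdentificationResult:
    """Select exactly one model of the collection for query q.

    ``method`` is APMI, CPMI or DMS (case-insensitive), or one of the named
    registry variants such as "3-apmi".  When the Pareto front has a single
    point the choice is trivial and all methods agree on its model.  When the
    query's id matches a table row, that row is excluded (leave-self-out).
    """
    key = method.lower()
    if key in METHOD_REGISTRY:
        method_name, reg_params = METHOD_REGISTRY[key]
        params = params or reg_params
    else:
        method_name = method.upper()
    if method_name not in {"APMI", "CPMI", "DMS"}:
        raise ValidationError(f"unknown identification method: {method!r}")
    if params is None and method_name != "DMS":
        params = NeighbourhoodParams()

    if method_name == "APMI":
        result = apmi(T, q, params, distances=distances)
    elif method_name == "CPMI":
        result = cpmi(T, q, params, distances=distances)
    else:
        result = dms(T, q, distances=distances)

    if attach_prediction:
        row = T.row_index(q.id)
        if row is not None:
            j = T.model_index(result.selected_model)
            pred = T.predictions[row, j]
            if math.isfinite(pred):
                result = dataclasses.replace(result, prediction=float(pred))
    return result
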