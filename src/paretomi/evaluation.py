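"""Evaluation of identification methods: oracle, LOO protocol, metrics.

Identification is scored two ways.  As a *classification* problem, each
method's selected model per chemical is compared with the oracle label (the
model with minimal absolute error for that chemical — the a-priori best
choice, an upper bound no method can beat).  As a *regression* problem, the
selected model's stored prediction for each chemical forms the partitioning
model's prediction vector, scored against the measured activities with
R2/RSE/Q2/MAE/RMSE.

R2 is the squared Pearson correlation of observed and predicted values, and
RSE the residual standard error of the simple linear regression of observed
on predicted.  Both are therefore invariant under affine transformations of
the predictions — two models that are affine functions of the same single
descriptor share R2 and RSE exactly, while Q2/MAE/RMSE, which compare
predictions to observations directly, differ.  Q2 uses the evaluated-set
mean: Q2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, ValidationError
from .identification import (
    IdentificationResult,
    NeighbourhoodParams,
    identify,
)
from .models import Chemical, ModelTable

__all__ = [
    "OracleLabels",
    "ClassificationReport",
    "RegressionReport",
    "LOOReport",
    "oracle_labels",
    "classification_metrics",
    "regression_metrics",
    "pairwise_distance_matrix",
    "similarity_activity_table",
    "loo_evaluate",
]


@dataclass(frozen=True)
class OracleLabels:
    """Per-chemical a-priori best model (row-wise error argmin)."""

    labels: dict[str, str]
    ties: tuple[str, ...] = ()  # chemical ids where the argmin was not unique


@dataclass(frozen=True)
class ClassificationReport:
    correct: int
    false_positive: int
    false_negative: int
    accuracy: float
    positive_class: str
    n: int


@dataclass(frozen=True)
class RegressionReport:
    r2: float
    rse: float
    q2: float
    mae: float
    rmse: float
    n: int


@dataclass(frozen=True)
class LOOReport:
    classification: ClassificationReport
    # None when the table is too small for regression statistics (< 3 rows)
    regression: RegressionReport | None
    per_query: tuple[IdentificationResult, ...]
    method: str
    params: NeighbourhoodParams | None = None
    tie_break_log: tuple[str, ...] = ()


def oracle_labels(T: ModelTable) -> OracleLabels:
    """Best model per chemical by minimal absolute error; ties take model order."""
    labels: dict[str, str] = {}
    ties: list[str] = []
    for i, chem in enumerate(T.chemicals):
        errs = np.where(np.isfinite(T.errors[i, :]), T.errors[i, :], np.inf)
        j = int(np.argmin(errs))
        labels[chem.id] = T.model_names[j]
        if int(np.sum(errs == errs[j])) > 1:
            ties.append(chem.id)
    return OracleLabels(labels=labels, ties=tuple(ties))


def classification_metrics(
    predicted: Mapping[str, str],
    oracle: OracleLabels,
    positive_class: str,
) -> ClassificationReport:
    """Confusion counts of predicted labels against the oracle.

    FP = predicted positive, oracle negative; FN = predicted negative,
    oracle positive.  For collections of more than two models this is the
    one-vs-rest report for ``positive_class``.
    """
    if not predicted:
        raise EmptyInputError("no predicted labels")
    known = set(oracle.labels.values()) | set(predicted.values())
    if positive_class not in known:
        raise ValidationError(f"positive class {positive_class!r} not among models")
    correct = fp = fn = 0
    for cid, pred in predicted.items():
        truth = oracle.labels[cid]
        if pred == truth:
            correct += 1
        elif pred == positive_class:
            fp += 1
        elif truth == positive_class:
            fn += 1
    n = len(predicted)
    return ClassificationReport(
        correct=correct,
        false_positive=fp,
        false_negative=fn,
        accuracy=correct / n,
        positive_class=positive_class,
        n=n,
    )


def regression_metrics(
    observed: Sequence[float], predicted: Sequence[float]
) -> RegressionReport:
    """R2, RSE, Q2, MAE, RMSE of a prediction vector against observations."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError("observed and predicted must have equal length")
    n = y.size
    if n < 3:
        raise ValidationError("regression metrics require at least 3 points")
    if np.ptp(y) == 0:
        raise ValidationError("constant observed vector: correlation undefined")

    resid = y - yhat
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - float(np.sum(resid**2)) / ss_tot

    if np.ptp(yhat) == 0:
        # degenerate constant predictions: no linear relation to speak of
        r2, rse = 0.0, float(np.sqrt(ss_tot / max(n - 2, 1)))
    else:
        fit = stats.linregress(yhat, y)
        r2 = float(fit.rvalue**2)
        fitted = fit.intercept + fit.slope * yhat
        rse = float(np.sqrt(np.sum((y - fitted) ** 2) / (n - 2)))
    return RegressionReport(r2=r2, rse=rse, q2=q2, mae=mae, rmse=rmse, n=n)


def pairwise_distance_matrix(chemicals: Sequence[Chemical]) -> np.ndarray:
    """Symmetric Tanimoto-distance matrix over a chemical list."""
    F = np.stack([c.fingerprint.array for c in chemicals]).astype(np.int32)
    inter = F @ F.T
    counts = F.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    return 1.0 - inter / union


def similarity_activity_table(
    chemicals: Sequence[Chemical],
    sim_thresholds: Sequence[float],
    act_thresholds: Sequence[float],
) -> pd.DataFrame:
    """Cumulative pair counts by distance and activity-difference thresholds.

    Over all unordered chemical pairs, cell (r, c) counts pairs whose
    Tanimoto distance is <= sim_thresholds[r] AND whose absolute activity
    difference is <= act_thresholds[c].  Thresholds are inclusive so that the
    (0, 0) cell counts identical-fingerprint, identical-activity pairs.
    """
    chems = list(chemicals)
    if len(chems) < 2:
        raise EmptyInputError("pairwise analysis needs at least two chemicals")
    D = pairwise_distance_matrix(chems)
    acts = np.array([c.activity for c in chems])
    iu, ju = np.triu_indices(len(chems), k=1)
    d = D[iu, ju]
    delta = np.abs(acts[iu] - acts[ju])
    counts = np.empty((len(sim_thresholds), len(act_thresholds)), dtype=int)
    for r, st in enumerate(sim_thresholds):
        within = d <= st
        for c, at in enumerate(act_thresholds):
            counts[r, c] = int(np.sum(within & (delta <= at)))
    return pd.DataFrame(counts, index=list(sim_thresholds), columns=list(act_thresholds))


def loo_evaluate(
    T: ModelTable,
    method: str = "3-apmi",
    params: NeighbourhoodParams | None = None,
    positive_class: str | None = None,
) -> LOOReport:
    """Leave-one-out evaluation of an identification method over a table.

    Each chemical in turn plays the query; the remaining chemicals drive the
    identification (the query's own row never contributes vectors).  The
    special method ``"oracle"`` scores the a-priori best selector itself and
    bounds every real method from above.
    """
    if T.n_chemicals < 2:
        raise ValidationError("leave-one-out requires at least two chemicals")
    oracle = oracle_labels(T)
    positive = positive_class or T.model_names[0]
    D = pairwise_distance_matrix(T.chemicals)

    predicted: dict[str, str] = {}
    results: list[IdentificationResult] = []
    logs: list[str] = []
    yhat = np.empty(T.n_chemicals)
    for i, chem in enumerate(T.chemicals):
        if method.lower() == "oracle":
            sel = oracle.labels[chem.id]
            res = IdentificationResult(
                query_id=chem.id,
                method="ORACLE",
                selected_model=sel,
                neighbourhood=None,
                prediction=float(T.predictions[i, T.model_index(sel)]),
            )
        else:
            res = identify(T, chem, method=method, params=params, distances=D[i])
        predicted[chem.id] = res.selected_model
        yhat[i] = T.predictions[i, T.model_index(res.selected_model)]
        results.append(res)
        logs.extend(res.tie_break_log)

    cls = classification_metrics(predicted, oracle, positive)
    reg = regression_metrics(T.activities, yhat) if T.n_chemicals >= 3 else None
    used_params = params
    if used_params is None and method.lower() in {
        "3-apmi", "5-apmi", "3-cpmi", "5-cpmi", "10-cpmi"
    }:
        from .identification import METHOD_REGISTRY

        used_params = METHOD_REGISTRY[method.lower()][1]
    return LOOReport(
        classification=cls,
        regression=reg,
        per_query=tuple(results),
        method=method,
        params=used_params,
        tie_break_log=tuple(logs),
    )
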