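"""Chemicals, linear QSAR models, and the model table.

The model table is the central array of the framework: one row per chemical
(identifier, fingerprint, measured activity, optional logP/SMILES) and one
prediction column per model in the collection, with the absolute error
matrix derived from them.  Predictions may come from bundled providers
(e.g. the PN/NPN narcosis models below) or be loaded as literal columns —
outputs of external software are accepted as data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import EmptyInputError, MissingDescriptorError, ValidationError
from .similarity import Fingerprint

__all__ = [
    "Chemical",
    "LinearQSARModel",
    "ModelTable",
    "NPN_MODEL",
    "PN_MODEL",
    "linear_qsar_predict",
    "build_model_table",
]

PredictionProvider = Callable[["Chemical"], float]


@dataclass(frozen=True)
class Chemical:
    """One chemical compound: structure, measured activity, optional descriptors."""

    id: str
    fingerprint: Fingerprint
    activity: float
    logp: float | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.activity):
            raise ValidationError(f"chemical {self.id}: non-finite activity")


@dataclass(frozen=True)
class LinearQSARModel:
    """Affine one-descriptor QSAR model: prediction = slope * logP + intercept."""

    name: str
    slope: float
    intercept: float

    def __call__(self, chemical: Chemical) -> float:
        if chemical.logp is None:
            raise MissingDescriptorError(
                f"model {self.name}: chemical {chemical.id} has no logP value"
            )
        return linear_qsar_predict(self, chemical.logp)


def linear_qsar_predict(model: LinearQSARModel, logp: float) -> float:
    """Evaluate an affine logP model: slope * logP + intercept."""
    if not math.isfinite(logp):
        raise ValidationError(f"model {model.name}: non-finite logP")
    return model.slope * logp + model.intercept


# Narcosis models for Tetrahymena pyriformis toxicity, log(1/IGC50) from logP.
NPN_MODEL = LinearQSARModel("NPN", slope=0.83, intercept=-2.07)  # non-polar narcosis
PN_MODEL = LinearQSARModel("PN", slope=0.62, intercept=-1.00)  # polar narcosis


class ModelTable:
    """Chemicals x models array of predictions and absolute errors.

    ``predictions[i, j]`` is model j's prediction for chemical i (NaN when the
    model makes no prediction for that chemical; such pairs never become
    Pareto vectors).  ``errors`` is always ``|activity - prediction|``,
    recomputed from the inputs and never trusted from file.
    """

    def __init__(
        self,
        chemicals: Sequence[Chemical],
        model_names: Sequence[str],
        predictions: np.ndarray,
    ) -> None:
        chemicals = list(chemicals)
        model_names = list(model_names)
        if not chemicals:
            raise EmptyInputError("model table requires at least one chemical")
        if len(model_names) < 2:
            raise ValidationError("model table requires at least two models")
        ids = [c.id for c in chemicals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate chemical ids: {dupes}")
        if len(set(model_names)) != len(model_names):
            raise ValidationError("duplicate model names")
        predictions = np.asarray(predictions, dtype=float)
        if predictions.shape != (len(chemicals), len(model_names)):
            raise ValidationError(
                f"prediction matrix shape {predictions.shape} does not match "
                f"{len(chemicals)} chemicals x {len(model_names)} models"
            )
        widths = {len(c.fingerprint) for c in chemicals}
        if len(widths) != 1:
            raise ValidationError(f"inconsistent fingerprint widths: {sorted(widths)}")

        self.chemicals = chemicals
        self.model_names = model_names
        self.predictions = predictions
        activities = np.array([c.activity for c in chemicals])
        self.errors = np.abs(activities[:, None] - predictions)
        self._index = {c.id: i for i, c in enumerate(chemicals)}

    @property
    def n_chemicals(self) -> int:
        return len(self.chemicals)

    @property
    def n_models(self) -> int:
        return len(self.model_names)

    @property
    def activities(self) -> np.ndarray:
        return np.array([c.activity for c in self.chemicals])

    def row_index(self, chemical_id: str) -> int | None:
        return self._index.get(chemical_id)

    def chemical(self, chemical_id: str) -> Chemical:
        idx = self._index.get(chemical_id)
        if idx is None:
            raise KeyError(chemical_id)
        return self.chemicals[idx]

    def model_index(self, model_name: str) -> int:
        try:
            return self.model_names.index(model_name)
        except ValueError:
            raise KeyError(model_name) from None


def build_model_table(
    chemicals: Sequence[Chemical],
    models: Sequence[PredictionProvider | LinearQSARModel],
    model_names: Sequence[str] | None = None,
) -> ModelTable:
    """Fill a model table by running each prediction provider on each chemical.

    Providers are any callables Chemical -> float; a provider failure is
    reported with the chemical id and the model name.
    """
    chemicals = list(chemicals)
    if not chemicals:
        raise EmptyInputError("build_model_table requires at least one chemical")
    if model_names is None:
        model_names = [getattr(m, "name", f"M{i + 1}") for i, m in enumerate(models)]
    preds = np.empty((len(chemicals), len(models)))
    for j, (model, name) in enumerate(zip(models, model_names)):
        for i, chem in enumerate(chemicals):
            try:
                preds[i, j] = float(model(chem))
            except MissingDescriptorError:
                raise
            except Exception as exc:  # surface which pair failed
                raise ValidationError(
                    f"model {name} failed on chemical {chem.id}: {exc}"
                ) from exc
    return ModelTable(chemicals, model_names, preds)
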