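"""Synthetic clustered chemical datasets and the printed worked examples.

The generator emulates the structure the identification method assumes of
real chemical data: chemical space falls into structural clusters (each
chemical's fingerprint is a noisy copy of its cluster's prototype
bitstring), activity within a cluster follows a cluster-specific affine law
of one latent descriptor, and the model collection contains one specialist
per cluster — exact on its own cluster, systematically biased elsewhere.
Ground-truth cluster labels are returned separately and are never written
into the model-table CSV: identification must not see them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .models import Chemical, ModelTable
from .similarity import Fingerprint

__all__ = ["SyntheticConfig", "generate_dataset", "table3_fixture", "table4_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    flip_prob is the per-bit probability that a chemical's fingerprint
    differs from its cluster prototype; local_noise_sd the Gaussian sd of
    activity noise around the cluster's affine law; foreign_bias the
    systematic error a model incurs on chemicals outside its own cluster.
    """

    n_chemicals: int = 500
    n_bits: int = 256
    n_clusters: int = 4
    flip_prob: float = 0.05
    n_models: int = 4
    local_noise_sd: float = 0.1
    foreign_bias: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_chemicals, self.n_bits, self.n_clusters, self.n_models) < 1:
            raise ValidationError("all counts must be positive")
        if not (0.0 < self.flip_prob < 0.5):
            raise ValidationError("flip_prob must lie in (0, 0.5)")
        if self.local_noise_sd < 0:
            raise ValidationError("local_noise_sd must be non-negative")
        if self.n_clusters > self.n_models:
            raise ValidationError("need at least one model per cluster")


# latent descriptor range: a logP-like lipophilicity scale
_DESCRIPTOR_RANGE = (0.0, 5.0)
# cluster affine-law coefficient ranges (slope, intercept)
_SLOPE_RANGE = (0.5, 1.5)
_INTERCEPT_RANGE = (-2.0, 0.0)


def generate_dataset(cfg: SyntheticConfig) -> tuple[ModelTable, np.ndarray]:
    """Generate a clustered model table plus hidden cluster labels.

    Deterministic under ``cfg.seed``.  Model k applies cluster k's true
    affine law to every chemical's descriptor and additionally incurs
    ``foreign_bias`` on chemicals from other clusters, so the a-priori best
    model of a chemical coincides with its cluster in the low-noise limit.
    """
    rng = np.random.default_rng(cfg.seed)

    prototypes = rng.integers(0, 2, size=(cfg.n_clusters, cfg.n_bits))
    for k in range(cfg.n_clusters):
        while not prototypes[k].any():
            warnings.warn(f"all-zero prototype for cluster {k}; regenerating")
            prototypes[k] = rng.integers(0, 2, size=cfg.n_bits)

    clusters = rng.integers(0, cfg.n_clusters, size=cfg.n_chemicals)
    flips = rng.random((cfg.n_chemicals, cfg.n_bits)) < cfg.flip_prob
    bits = prototypes[clusters] ^ flips.astype(int)
    # a chemical whose every bit flipped off would be featureless; force one bit
    dead = ~bits.any(axis=1)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} all-zero fingerprints; setting one bit")
        bits[dead, 0] = 1

    slopes = rng.uniform(*_SLOPE_RANGE, size=cfg.n_clusters)
    intercepts = rng.uniform(*_INTERCEPT_RANGE, size=cfg.n_clusters)
    descriptor = rng.uniform(*_DESCRIPTOR_RANGE, size=cfg.n_chemicals)
    noise = rng.normal(0.0, cfg.local_noise_sd, size=cfg.n_chemicals)
    activity = slopes[clusters] * descriptor + intercepts[clusters] + noise

    predictions = np.empty((cfg.n_chemicals, cfg.n_models))
    for k in range(cfg.n_models):
        law_k = slopes[k % cfg.n_clusters] * descriptor + intercepts[k % cfg.n_clusters]
        off_cluster = clusters != (k % cfg.n_clusters)
        predictions[:, k] = law_k + cfg.foreign_bias * off_cluster

    chemicals = [
        Chemical(
            id=f"C{i:04d}",
            fingerprint=Fingerprint(tuple(int(b) for b in bits[i])),
            activity=float(activity[i]),
            logp=float(descriptor[i]),
        )
        for i in range(cfg.n_chemicals)
    ]
    model_names = [f"M{k + 1}" for k in range(cfg.n_models)]
    return ModelTable(chemicals, model_names, predictions), clusters


# ---------------------------------------------------------------------------
# Worked neighbourhood examples: distances to the query and both narcosis
# models' absolute errors for each neighbour, with the selection the
# average-error rule must reproduce.

#: 3-Pareto neighbourhood of 3-Phenyl-1-propanol: (name, distance, PN err, NPN err)
TABLE3_ROWS = (
    ("Methylbenzene", 0.33, 0.37, 0.28),
    ("4-Dimethylbenzene", 0.36, 0.54, 0.08),
    ("4-Chloro-3-methylphenol", 0.30, 0.61, 1.14),
)
TABLE3_EXPECTED = "NPN"

#: 3-Pareto neighbourhood of Benzylamine
TABLE4_ROWS = (
    ("2-Chloroaniline", 0.08, 0.30, 0.38),
    ("(+/-)-1,2-Diphenyl-2-propanol", 0.11, 0.041, 0.59),
)
TABLE4_EXPECTED = "PN"

_FIXTURE_WIDTH = 128  # synthetic fingerprints engineered to hit printed distances


def _fingerprint_at_distance(distance: float) -> Fingerprint:
    """A synthetic fingerprint at the given Tanimoto distance from the
    100-on-bit query fingerprint: the first round(100*(1-distance)) query
    bits, so intersection = on-bit count and union = 100 exactly."""
    c = round(100 * (1.0 - distance))
    bits = [1] * c + [0] * (_FIXTURE_WIDTH - c)
    return Fingerprint(tuple(bits))


def _query_fingerprint() -> Fingerprint:
    return Fingerprint(tuple([1] * 100 + [0] * (_FIXTURE_WIDTH - 100)))


def _worked_example(rows, query_id: str) -> tuple[ModelTable, Chemical]:
    """Materialise a printed neighbourhood as a model table plus query.

    Fingerprints are synthetic stand-ins engineered so the Tanimoto
    distance to the query equals the printed distance; activities are set
    to 1 and predictions back-computed so the recomputed absolute errors
    equal the printed PN/NPN errors.
    """
    chemicals = []
    predictions = []
    for name, dist, e_pn, e_npn in rows:
        chemicals.append(
            Chemical(
                id=name,
                fingerprint=_fingerprint_at_distance(dist),
                activity=1.0,
            )
        )
        predictions.append([1.0 - e_pn, 1.0 - e_npn])
    table = ModelTable(chemicals, ["PN", "NPN"], np.array(predictions))
    query = Chemical(id=query_id, fingerprint=_query_fingerprint(), activity=1.0)
    return table, query


def table3_fixture() -> tuple[ModelTable, Chemical, str]:
    """Worked example A: the 3-Phenyl-1-propanol neighbourhood -> NPN."""
    table, query = _worked_example(TABLE3_ROWS, "3-Phenyl-1-propanol")
    return table, query, TABLE3_EXPECTED


def table4_fixture() -> tuple[ModelTable, Chemical, str]:
    """Worked example B: the Benzylamine neighbourhood -> PN."""
    table, query = _worked_example(TABLE4_ROWS, "Benzylamine")
    return table, query, TABLE4_EXPECTED
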