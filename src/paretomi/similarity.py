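"""Binary fingerprints and Tanimoto similarity/distance.

Fingerprints are consumed precomputed (bitstrings in CSV): hashed
fingerprints are toolkit- and version-dependent, and the identification
machinery must be reproducible without a chemistry toolkit.  An optional
adapter that populates bitstrings from SMILES via RDKit is provided for
convenience but is not part of the core contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FingerprintError, ZeroFingerprintError

__all__ = ["Fingerprint", "tanimoto", "tanimoto_distance", "smiles_to_fingerprint"]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width binary structural fingerprint.

    ``bits`` is stored as a tuple of 0/1 ints; ``length`` is the declared
    dataset-wide width.  All-zero fingerprints are rejected at construction:
    a featureless molecule cannot participate in similarity search (its
    Tanimoto coefficient is 0/0).
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits:
            raise FingerprintError("empty fingerprint")
        if any(b not in (0, 1) for b in self.bits):
            raise FingerprintError("fingerprint bits must be 0 or 1")
        if not any(self.bits):
            raise ZeroFingerprintError(
                "all-zero fingerprint: Tanimoto similarity undefined"
            )

    @classmethod
    def from_string(cls, s: str) -> "Fingerprint":
        """Parse a '0'/'1' bitstring, e.g. a 1024-character CSV field."""
        if set(s) - {"0", "1"}:
            raise FingerprintError(f"non-binary characters in fingerprint: {s[:32]!r}...")
        return cls(tuple(int(c) for c in s))

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)


def _check_pair(a: Fingerprint, b: Fingerprint) -> None:
    if len(a) != len(b):
        raise FingerprintError(
            f"fingerprint length mismatch: {len(a)} vs {len(b)}"
        )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| in [0, 1].

    Symmetric; equals 1 exactly when the fingerprints are identical (all-zero
    fingerprints are excluded at construction, so the ratio is well defined).
    """
    _check_pair(a, b)
    av, bv = a.array, b.array
    inter = int(np.count_nonzero(av & bv))
    union = int(np.count_nonzero(av | bv))
    return inter / union


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Distance 1 - Tanimoto(a, b), the first Pareto coordinate."""
    return 1.0 - tanimoto(a, b)


def smiles_to_fingerprint(smiles: str, n_bits: int = 1024) -> Fingerprint:
    """Optional RDKit adapter: hashed path-based fingerprint from SMILES.

    Bit values depend on the installed RDKit version; use only when
    precomputed fingerprints are unavailable.
    """
    from rdkit import Chem  # deferred: core must not require a toolkit
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(tuple(int(fp.GetBit(i)) for i in range(n_bits)))
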