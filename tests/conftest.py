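import numpy as np
import pytest

from paretomi import Chemical, Fingerprint, ModelTable, TaggedPoint, Vector2D


def tag(d, e, cid="c", mid="m"):
    return TaggedPoint(Vector2D(float(d), float(e)), cid, mid)


def tags(coords):
    """Distinct-tagged points from a coordinate list (duplicates allowed)."""
    return [tag(d, e, cid=f"c{i}", mid="m") for i, (d, e) in enumerate(coords)]


def random_tagged_points(rng, n, resolution=8):
    """Random points on a coarse grid so coordinate ties and duplicates occur."""
    d = rng.integers(0, resolution, n) / resolution
    e = rng.integers(0, resolution, n) / resolution
    return tags(list(zip(d, e)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def fp(bits):
    return Fingerprint(tuple(int(b) for b in bits))


@pytest.fixture
def toy_table():
    """3 chemicals x 2 models with hand-checkable errors."""
    chems = [
        Chemical("a", fp("11110000"), activity=1.0),
        Chemical("b", fp("11001100"), activity=2.0),
        Chemical("c", fp("00001111"), activity=0.5),
    ]
    preds = np.array([[1.0, 0.0], [1.5, 2.5], [0.5, 1.5]])
    return ModelTable(chems, ["M1", "M2"], preds)
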