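import numpy as np
import pandas as pd
import pytest

from plantpatch.labels import CLASSES

# Published per-class annotation counts of the real corpus the pipeline
# was designed around; used for dataset-arithmetic checks.
CORPUS_COUNTS = {
    "background": 44_872,
    "leaf": 7_942,
    "branch": 5_426,
    "flower": 2_488,
    "pod": 839,
    "bud": 736,
}


@pytest.fixture(scope="session")
def corpus_counts():
    return dict(CORPUS_COUNTS)


@pytest.fixture(scope="session")
def corpus_table(corpus_counts):
    """A full-size annotation table with the published class counts."""
    labels = np.repeat(list(corpus_counts), list(corpus_counts.values()))
    n = len(labels)
    return pd.DataFrame(
        {
            "image_id": "corpus",
            "row": np.arange(n) // 1000,
            "col": np.arange(n) % 1000,
            "label": labels,
        }
    )


def make_patch(color, size=10, jitter=0, seed=0):
    """A size×size×3 uint8 patch of one color with optional uniform jitter."""
    rng = np.random.default_rng(seed)
    base = np.tile(np.asarray(color, dtype=np.int64), (size, size, 1))
    if jitter:
        base = base + rng.integers(-jitter, jitter + 1, size=base.shape)
    return np.clip(base, 0, 255).astype(np.uint8)


class StubModel:
    """A fake fitted classifier emitting fixed probability rows."""

    def __init__(self, classes, proba_fn):
        self.classes_ = np.asarray(classes)
        self._fn = proba_fn

    def predict_proba(self, X):
        return np.asarray([self._fn(x) for x in X], dtype=float)


@pytest.fixture
def stub_model_factory():
    return StubModel
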