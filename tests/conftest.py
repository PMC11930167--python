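import numpy as np
import pytest

from dbscanmaps import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_table(rng):
    """200 uniform points in a 500x500 nm square."""
    return LocalizationTable(
        x=rng.uniform(0, 500, size=200), y=rng.uniform(0, 500, size=200)
    )


def make_table(xy):
    xy = np.asarray(xy, dtype=float)
    return LocalizationTable(x=xy[:, 0], y=xy[:, 1])
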