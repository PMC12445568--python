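import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thalscreen.dominance import Criterion, DecisionTable
from thalscreen.fixtures import fixture_worked_example, worked_example_frame

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def worked_example() -> DecisionTable:
    return fixture_worked_example()


@pytest.fixture
def worked_frame() -> pd.DataFrame:
    return worked_example_frame()


def make_table(rows, dirs, ids=None):
    """Build a DecisionTable from [(values..., cls)] rows and a direction map.

    ``dirs`` is an ordered {name: direction} mapping; values follow its order.
    """
    names = list(dirs)
    ids = ids if ids is not None else [f"o{i}" for i in range(len(rows))]
    frame = pd.DataFrame(
        [list(r[:-1]) + [r[-1]] for r in rows], columns=names + ["decision"], index=ids
    )
    return DecisionTable(frame, [Criterion(n, d) for n, d in dirs.items()])


def to_oracle(table: DecisionTable):
    """Convert a package DecisionTable to the oracle's plain structures."""
    dirs = {c.name: c.direction for c in table.criteria}
    rows = []
    for oid in table.object_ids:
        values = {c.name: float(table.data.loc[oid, c.name]) for c in table.criteria}
        cls = int(table.data.loc[oid, table.decision_col])
        rows.append((oid, values, cls))
    return rows, dirs


def random_table(rng: np.random.Generator, max_objects=12, max_criteria=4):
    """A random small decision table with mixed directions and binary labels.

    Values are drawn from a small integer grid so ties and dominance
    relations actually occur.
    """
    n = int(rng.integers(2, max_objects + 1))
    m = int(rng.integers(1, max_criteria + 1))
    dirs = {
        f"c{j}": ("gain" if rng.random() < 0.5 else "cost") for j in range(m)
    }
    values = rng.integers(0, 4, size=(n, m)).astype(float)
    labels = rng.integers(0, 2, size=n)
    rows = [tuple(values[i]) + (int(labels[i]),) for i in range(n)]
    return make_table(rows, dirs)
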