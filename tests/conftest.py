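import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lesioneval.locations import ClassificationParams
from lesioneval.synthetic import PhantomSpec, make_anatomy, plant_lesions


@pytest.fixture(scope="session")
def anatomy():
    return make_anatomy(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom(anatomy):
    """One planted phantom: (reference label map, truth table)."""
    return plant_lesions(anatomy, PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def params():
    return ClassificationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def long_table(x: np.ndarray, runs_axis: bool = False, metric: str = "volume_ml") -> pd.DataFrame:
    """Build a long-format measurement table from an array.

    2D (subjects x scanners): run-1 values. 3D (subjects x scanners x runs).
    """
    rows = []
    if x.ndim == 2:
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                rows.append((f"s{i:02d}", f"sc{j}", 1, metric, float(x[i, j])))
    else:
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                for r in range(x.shape[2]):
                    rows.append((f"s{i:02d}", f"sc{j}", r + 1, metric, float(x[i, j, r])))
    return pd.DataFrame(rows, columns=["subject", "scanner", "run", "metric", "value"])
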