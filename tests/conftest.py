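import numpy as np
import pandas as pd
import pytest

from braintraj.core import VolumeMatrix
from braintraj.taxonomy import default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def reference_means():
    from braintraj.datasets import reference_bin_means

    return reference_bin_means()


@pytest.fixture()
def tiny_matrix():
    """Two subjects, two bilateral regions, handmade numbers."""
    meta = pd.DataFrame(
        {"cohort": ["Korean", "IXI"], "age": [25, 67], "sex": ["M", "F"]},
        index=pd.Index(["s1", "s2"], name="subject_id"),
    )
    volumes = pd.DataFrame(
        {"Hippocampus": [8768.0, 8500.0], "Brain Stem": [20063.7, 20500.0]},
        index=meta.index,
    )
    return VolumeMatrix(volumes, meta)


def random_lateralized_matrix(rng: np.random.Generator, n_subjects: int = 10) -> VolumeMatrix:
    """Random volumes over the full 95-structure lateralized roster."""
    tax = default_taxonomy()
    names = [r.name for r in tax.regions]
    meta = pd.DataFrame(
        {
            "cohort": rng.choice(["A", "B"], n_subjects),
            "age": rng.integers(21, 91, n_subjects),
            "sex": rng.choice(["M", "F"], n_subjects),
        },
        index=pd.Index([f"s{i}" for i in range(n_subjects)], name="subject_id"),
    )
    volumes = pd.DataFrame(
        rng.uniform(5000.0, 50000.0, size=(n_subjects, len(names))), index=meta.index, columns=names
    )
    return VolumeMatrix(volumes, meta)
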