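import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rgdfusion.cohort import preprocess_volume
from rgdfusion.phantom import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20-phantom cohort (10/class) preprocessed to 128x128x8."""
    cohort = generate_cohort(PhantomSpec(n_per_class=10, seed=7))
    X = np.stack([preprocess_volume(v).voxels for v, _, _ in cohort])
    y = np.array([label for _, label, _ in cohort])
    patients = np.array([pid for _, _, pid in cohort])
    return X, y, patients


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
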