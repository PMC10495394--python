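import numpy as np
import pandas as pd
import pytest

from pkdistill import ParameterRanges, sample_virtual_drugs
from pkdistill.ranges import FEATURE_COLUMNS, LABEL_COLUMNS


@pytest.fixture(scope="session")
def small_library() -> pd.DataFrame:
    """A 100-drug library shared by simulator-facing tests."""
    return sample_virtual_drugs(ParameterRanges(), n=100, seed=1234)


def make_reference_drug(**overrides) -> pd.Series:
    """A mid-range drug whose every property can be pinned by tests."""
    base = {
        "id": "ref",
        "molecular_mass": 300.0,
        "molar_volume": 200.0,
        "pka": 7.0,
        "particle_radius": 20.0,
        "drug_density": 0.4,
        "solubility": 10.0,
        "precipitation_rate": 0.1,
        "effective_permeability": 2.0,
        **{f"fupc_{t}": 1.0 for t in
           ("stomach", "duodenum", "jejunum", "ileum", "colon",
            "liver", "kidney", "rest")},
        "body_mass": 70.0,
        "dose": 5000.0,
        "km": 1.0,
        "vmax": 1e-4,
    }
    base.update(overrides)
    return pd.Series(base)


@pytest.fixture
def reference_drug() -> pd.Series:
    return make_reference_drug()


def make_synthetic_dataset(
    n: int = 400, n_features: int = 10, seed: int = 0, noise: float = 0.0
):
    """Features uniform on [0,1]; all three labels depend only on f0 and f1.

    Used for planted-signal recovery tests: an ideal feature-reduction
    search should isolate f0 and f1.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=(n, n_features))
    cols = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(x, columns=cols, index=[f"d{i}" for i in range(n)])
    y = {
        "cmax_over_dose": x[:, 0] + x[:, 1],
        "tmax": x[:, 0] * x[:, 1],
        "auc_over_dose": x[:, 0] - 0.5 * x[:, 1],
    }
    for name, vals in y.items():
        vals = vals + noise * rng.normal(size=n)
        lo, hi = vals.min(), vals.max()
        df[name] = (vals - lo) / (hi - lo)
    return df, cols
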