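import numpy as np
import pandas as pd
import pytest

from ftmspeaks import SynthSpec, build_dataset, synthetic_dataset


@pytest.fixture
def table1_tables():
    """Tiny two-peak, two-sample study in the three-table input format."""
    e_data = pd.DataFrame(
        {
            "mass": [221.06665, 222.00432],
            "sample 1": [1152257.5, 2158339.3],
            "sample 2": [1812663.0, 0.0],
        }
    )
    f_data = pd.DataFrame(
        {
            "sample": ["sample 1", "sample 2"],
            "Location": ["Michigan", "Wisconsin"],
            "Vegetation": ["Corn", "Switchgrass"],
        }
    )
    e_meta = pd.DataFrame(
        {
            "mass": [221.06665, 222.00432],
            "molecular formula": ["C8H14O7", "C9H5O6N1"],
        }
    )
    return e_data, f_data, e_meta


@pytest.fixture
def table1_dataset(table1_tables):
    e_data, f_data, e_meta = table1_tables
    return build_dataset(
        e_data, f_data, e_meta,
        peak_id="mass", sample_id="sample", formula="molecular formula",
    )


@pytest.fixture(scope="session")
def synth_default():
    """One grouped synthetic study at the default scale, with its truth table."""
    return synthetic_dataset(SynthSpec(seed=11))


@pytest.fixture(scope="session")
def synth_small():
    """A quick 300-peak study for per-test filtering/comparison work."""
    return synthetic_dataset(
        SynthSpec(n_peaks=300, n_samples=12, n_groups=2, seed=5,
                  formula_assignment_rate=0.7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
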