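import numpy as np
import pandas as pd
import pytest

from questmri.synthetic import (AcquisitionProtocol, CoilFieldSpec, NoiseSpec,
                                two_region_phantom)


@pytest.fixture(scope="session")
def small_protocol():
    """Default TR schedule on a small 48x48 matrix for fast tests."""
    return AcquisitionProtocol(matrix=(48, 48))


@pytest.fixture(scope="session")
def noiseless_setup(small_protocol):
    """Two-region phantom, uniform coil, no noise, no jitter."""
    phantom = two_region_phantom((48, 48), r1_left=0.2, r1_right=0.4)
    coil = CoilFieldSpec()
    noise = NoiseSpec(model="none", sigma=0.0, jitter_sigma=0.0, seed=0)
    return phantom, small_protocol, coil, noise


def make_group_table(cell_means, cell_sds, cell_ns, seed=0):
    """Build a (subject, group, ear, value) table from per-cell moments."""
    rng = np.random.default_rng(seed)
    rows = []
    for (group, ear), mean in cell_means.items():
        sd = cell_sds.get((group, ear), 0.0)
        n = cell_ns[(group, ear)]
        for k in range(n):
            rows.append({"subject": f"{group}-{k:02d}", "group": group,
                         "ear": ear,
                         "value": float(rng.normal(mean, sd)) if sd else mean})
    return pd.DataFrame(rows)


@pytest.fixture
def group_table_factory():
    return make_group_table
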