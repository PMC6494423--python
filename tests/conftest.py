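import numpy as np
import pandas as pd
import pytest

from mpskit import AnalysisConfig, LatticeParams, LocalizationTable


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def clean_lattice_params():
    """The reference near-perfect lattice: f=1, 5 nm jitter, 10 nm precision."""
    return LatticeParams(
        periodic_fraction=1.0, jitter_nm=5.0,
        loc_precision_xy_nm=10.0, loc_precision_z_nm=10.0,
    )


@pytest.fixture
def small_null_params():
    """Short, sparse axon with no lattice (complete spatial randomness)."""
    return LatticeParams(
        periodic_fraction=0.0, axon_length_um=7.6, density_per_um=300.0
    )


def table_from_xy(x, y, z=None, axon_id="ax0"):
    data = {"axon_id": [axon_id] * len(x), "x_nm": x, "y_nm": y}
    if z is not None:
        data["z_nm"] = z
    return LocalizationTable(pd.DataFrame(data))


@pytest.fixture
def three_point_table():
    return table_from_xy([0.0, 95.0, 190.0], [0.0, 0.0, 0.0])
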