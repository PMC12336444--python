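import numpy as np
import pandas as pd
import pytest

from ctcdx.cohort import reference_cohort


@pytest.fixture(scope="session")
def cohort():
    """The reconstructed 35-patient reference cohort."""
    table, sidecar = reference_cohort()
    return table


@pytest.fixture(scope="session")
def cohort_sidecar():
    return reference_cohort()[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_cell(area=60.0, dapi=1e4, ckmix=1e4, cd45=1e2, msln=1e4, cell_id="c0"):
    return pd.Series({"cell_id": cell_id, "area_um2": area, "int_dapi": dapi,
                      "int_ckmix": ckmix, "int_cd45": cd45, "int_msln": msln})
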