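import numpy as np
import pandas as pd
import pytest

from paleoforage import synth
from paleoforage.sdm import ClimateSlice
from paleoforage.spd import CalCurve


@pytest.fixture(scope="session")
def toy_curve() -> CalCurve:
    return synth.toy_cal_curve()


@pytest.fixture(scope="session")
def identity_curve() -> CalCurve:
    """mu(theta) = theta with zero curve error: calibration reduces to a
    Gaussian centered on the radiocarbon age."""
    theta = np.arange(5000.0, 26001.0, 10.0)
    return CalCurve(cal_bp=theta, c14_bp=theta.copy(), sigma=np.zeros_like(theta))


@pytest.fixture(scope="session")
def small_slice() -> ClimateSlice:
    cfg = synth.WorldConfig(n_rows=30, n_cols=40, seed=3)
    return synth.gen_climate_cube(cfg)[22000]


@pytest.fixture(scope="session")
def ranked_params() -> pd.DataFrame:
    """A small ranked prey table with p=0, c=0 so e* = e and h* = h."""
    from paleoforage import prey

    df = pd.DataFrame(
        {
            "species": ["alpha", "beta", "gamma"],
            "weight_kg": [100.0, 50.0, 10.0],
            "e_kcal": [1000.0, 500.0, 50.0],
            "h_hr": [1.0, 1.0, 1.0],
            "c_hr": [0.0, 0.0, 0.0],
            "p_fail": [0.0, 0.0, 0.0],
        }
    )
    return prey.rank_prey(df)
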