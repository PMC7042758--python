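import numpy as np
import pytest

from migconn.config import ModelConfig
from migconn.data_io import study_parasite_data
from migconn.model import (
    ConnectivityParams,
    IsotopeMixtureParams,
    ModelState,
    ParasiteParams,
    RecoveryProbs,
)
from migconn.simulate import TrueParams, simulate_bundle


@pytest.fixture(scope="session")
def model_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def table3():
    return study_parasite_data()


def small_true_params(seed=0) -> TrueParams:
    """Compact but informative generating parameters for fast fits."""
    m = np.array(
        [
            [0.10, 0.10, 0.10, 0.70],
            [0.10, 0.10, 0.20, 0.60],
            [0.30, 0.30, 0.10, 0.30],
            [0.30, 0.35, 0.05, 0.30],
            [0.30, 0.30, 0.10, 0.30],
            [0.50, 0.35, 0.05, 0.10],
            [0.55, 0.30, 0.05, 0.10],
            [0.50, 0.35, 0.05, 0.10],
        ]
    )
    state = ModelState(
        connectivity=ConnectivityParams.from_m(m),
        recovery=RecoveryProbs(r_ad=np.array([0.02, 0.015, 0.02]), r_juv=np.array([0.01, 0.008, 0.01])),
        isotopes=IsotopeMixtureParams(
            mu_s_d13c=0.97,
            theta=-1.5,
            mu_wce_d15n=0.2,
            mu_s_d15n=-0.3,
            sigma_c=np.array([0.8, 0.5]),
            sigma_n=np.array([0.9, 0.6]),
            rho=np.array([-0.33, 0.373]),
        ),
        parasites=ParasiteParams(
            f_nb=np.array(
                [
                    [0.02, 0.05, 0.01, 0.01, 0.01],
                    [0.01, 0.01, 0.10, 0.01, 0.04],
                    [0.01, 0.01, 0.12, 0.01, 0.01],
                    [0.01, 0.02, 0.01, 0.12, 0.01],
                ]
            ),
            a=1.5,
        ),
    )
    return TrueParams(
        state=state,
        N_ad=np.full(8, 2_000),
        N_juv=np.full(8, 3_000),
        n_unknown_ad=np.full(8, 10),
        n_unknown_juv=np.full(8, 10),
        n_iso=np.array([60, 80, 60]),
        H_nb=np.full((4, 5), 500),
        H_b=np.full((3, 5), 200),
    )


@pytest.fixture(scope="session")
def small_true():
    return small_true_params()


@pytest.fixture(scope="session")
def small_bundle(small_true):
    return simulate_bundle(small_true, seed=11)
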