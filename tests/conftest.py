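import numpy as np
import pytest

from celldosim import CellModel, ClusterModel, StoppingPowerTable
from celldosim.study import RunConfig, run_study


@pytest.fixture(scope="session")
def alpha_table():
    return StoppingPowerTable.for_particle("alpha")


@pytest.fixture(scope="session")
def beta_table():
    return StoppingPowerTable.for_particle("beta")


@pytest.fixture(scope="session")
def cell():
    return CellModel()


@pytest.fixture(scope="session")
def cluster():
    return ClusterModel.hcp()


@pytest.fixture(scope="session")
def study_result():
    """Full study at working statistics, shared by the regression tests.

    Alpha emitters run at the reference 10⁵ histories; beta emitters are
    scaled to 2×10⁵ (betas contribute <2% of any chain total, so the extra
    MC noise is far below the comparison tolerances).
    """
    cfg = RunConfig(
        histories_beta=200_000,
        cluster_histories_alpha=100_000,
        cluster_histories_beta=200_000,
        seed=20259,
    )
    return run_study(cfg)


@pytest.fixture(scope="session")
def simulated_table(study_result):
    return study_result.table
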