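import numpy as np
import pytest

from scicp.divisive_icp import DivisiveParams, run_divisive_icp
from scicp.icp_core import ICPParams
from scicp.synthetic_data import scenario_data


@pytest.fixture(scope="session")
def tiny_balanced():
    """Small balanced two-batch dataset with known types."""
    return scenario_data("balanced", "tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_params():
    """Fast divisive parameters for structural tests."""
    return DivisiveParams(K=4, L=2, n_groups=60, n_pcs=10, n_hvgs=120, icp=ICPParams())


@pytest.fixture(scope="session")
def tiny_multirun(tiny_balanced, tiny_params):
    X, meta, _ = tiny_balanced
    return run_divisive_icp(X, meta, tiny_params, seed=3)
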