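import numpy as np
import pytest

from lampcall import RunConfig, builtin_dye, standard_layout


@pytest.fixture(scope="session")
def pr_dye():
    return builtin_dye("PR")


@pytest.fixture(scope="session")
def hnb_dye():
    return builtin_dye("HNB")


@pytest.fixture(scope="session")
def small_layout():
    """A compact plate image (360x240) used for rendered-frame tests."""
    return standard_layout(360, 240)


@pytest.fixture
def short_config():
    """A 10-minute run at the standard 60-s cadence (11 frames)."""
    return RunConfig(run_name="test", total_assay_min=10.0, interval_s=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240271)
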