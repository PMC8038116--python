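import warnings

import pytest

import pectinsec as ps


@pytest.fixture(scope="session")
def truth_curve():
    """Ground-truth column calibration used by the generators."""
    return ps.truth_calibration()


@pytest.fixture(scope="session")
def fitted_curve(truth_curve):
    """Calibration refitted from a noise-free synthetic standards run."""
    standards = ps.simulate_standards_run(seed=1)
    return ps.fit_calibration(standards, ps.PULLULAN_MH, order=3)


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
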