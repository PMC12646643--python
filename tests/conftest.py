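import numpy as np
import pytest

from telinfer.cme import ParamVector
from telinfer.library import GridSpec, build_library
from telinfer.noise import CaptureModel


# Reduced 12-point-per-axis library over the production parameter ranges:
# full-range coarse surfaces and search bounds at a fraction of the 60^3 cost.
@pytest.fixture(scope="session")
def mini_grid():
    return GridSpec(n_points=12)


@pytest.fixture(scope="session")
def mini_library(mini_grid):
    return build_library(mini_grid, CaptureModel(1.0))


@pytest.fixture(scope="session")
def mini_library_beta03(mini_grid):
    # reuses the cached beta=1 CME solves; only the downsampling is new
    return build_library(mini_grid, CaptureModel(0.3))


@pytest.fixture(scope="session")
def theta_identifiable():
    # slow-switching, clearly bimodal regime
    return ParamVector(kon=0.05, koff=0.1, ksyn=10)


@pytest.fixture(scope="session")
def theta_weak():
    # very slow deactivation: broad compensation valley along kon/koff
    return ParamVector(kon=0.05, koff=0.01, ksyn=10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def bootstrap_identifiable(mini_library, theta_identifiable):
    """200 sampled replicates of 200 cells at the identifiable reference
    point, each refit by MLE."""
    from telinfer.synthetic import bootstrap_mles

    return bootstrap_mles(theta_identifiable, 200, 1.0, 200, 7, mini_library)


# Fine (continuous-nuisance) identifiability scans over a 3-per-axis
# sub-grid, shared by the landscape and sensitivity test suites.
@pytest.fixture(scope="session")
def fine_scan_beta1(mini_library):
    from telinfer.apriori import scan_landscape

    return scan_landscape(mini_library, N=1e4, subgrid=3)


@pytest.fixture(scope="session")
def fine_scan_beta03(mini_library_beta03):
    from telinfer.apriori import scan_landscape

    return scan_landscape(mini_library_beta03, N=1e4, subgrid=3)
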