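import numpy as np
import pytest

import pdtbind as pb


@pytest.fixture(scope="session")
def thermo():
    return pb.DEFAULT_THERMO


@pytest.fixture(scope="session")
def h2o_model():
    """Water-in-water coupling model (single mode, collisional)."""
    return pb.datasets.load_model("h2o-coupling")


@pytest.fixture(scope="session")
def host_model():
    """TEMOA-water host-coupling model (two modes)."""
    return pb.datasets.load_model("temoa-h2o-coupling")


@pytest.fixture(scope="session")
def coupling_sc():
    return pb.DEFAULT_COUPLING_SOFTCORE


@pytest.fixture(scope="session")
def transfer_sc():
    return pb.DEFAULT_TRANSFER_SOFTCORE


def pure_gaussian(mean, sigma, label="gaussian"):
    """Single-mode clash-free model (b = 1): the density is exactly normal."""
    return pb.CouplingModel(
        [
            pb.ModelMode(
                1.0,
                pb.GaussianParams(mean, sigma),
                pb.CollisionParams(1.0, 1.0, 1.0, 1.0),
            )
        ],
        label=label,
    )


@pytest.fixture(scope="session")
def gaussian_model():
    return pure_gaussian(2.41, 3.46)


@pytest.fixture(scope="session")
def wide_sc():
    """Soft-core far above the populated range: effectively the identity."""
    return pb.SoftCoreSpec(u_cut=500.0, u_max=1000.0)
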