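import numpy as np
import pytest

from rfcurrent import (
    BackgroundField,
    PatchGeometry,
    SequenceParams,
    WireGeometry,
    WireModelParams,
    build_slice_dictionary,
)


@pytest.fixture(scope="session")
def seq():
    return SequenceParams()


@pytest.fixture(scope="session")
def geom():
    return PatchGeometry()


@pytest.fixture(scope="session")
def dictionary(seq):
    # build once for the whole suite (about half a second)
    return build_slice_dictionary(seq, t1=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_wire_params(rng, i_range=(0.05, 0.3), xi_max_deg=45.0, offset=2.0):
    """One ground-truth parameter vector from the phantom regime."""
    return WireModelParams(
        i_rms=float(rng.uniform(*i_range)),
        phi_j_prime=float(rng.uniform(-np.pi, np.pi)),
        geometry=WireGeometry(
            float(rng.uniform(0.0, np.deg2rad(xi_max_deg))),
            float(rng.uniform(-np.pi, np.pi)),
            float(rng.uniform(-offset, offset)),
            float(rng.uniform(-offset, offset)),
        ),
        background=BackgroundField(
            float(rng.uniform(0.8, 1.2)),
            float(rng.uniform(-0.01, 0.01)),
            float(rng.uniform(-0.01, 0.01)),
        ),
    )
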