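import numpy as np
import pytest

from cmcdcm import (
    ExtrinsicTarget,
    InputSpec,
    IntrinsicTarget,
    MicrocircuitParams,
    ModulationSpec,
    NetworkModel,
    SimulationGrid,
    Source,
    default_network,
    make_leadfield,
)


@pytest.fixture(scope="session")
def params():
    return MicrocircuitParams()


@pytest.fixture(scope="session")
def small_grid():
    """A short, coarse window for fast dynamical tests."""
    return SimulationGrid(t_start=1.0, t_end=201.0, dt=4.0)


@pytest.fixture(scope="session")
def full_grid():
    from cmcdcm import default_grid

    return default_grid()


@pytest.fixture(scope="session")
def input_spec():
    return InputSpec()


def make_two_source_model(att_back=0.0, att_gain=0.0, exp_fwd=0.0):
    """Minimal A1 -> STG pair with one modulation target per kind."""
    sources = [Source("lA1", (-42, -22, 7), 1), Source("lSTG", (-60, -48, 20), 2)]
    af = np.array([[0.0, 0.0], [2.0, 0.0]])
    ab = np.array([[0.0, 0.5], [0.0, 0.0]])
    c = np.array([1.0, 0.0])
    mods = [
        ModulationSpec(
            "attention",
            extrinsic=[ExtrinsicTarget("lSTG", "lA1", "backward", b=att_back, tie="att_back")],
            intrinsic=[IntrinsicTarget("lA1", "II", g=att_gain, tie="att_gain")],
        ),
        ModulationSpec(
            "expectation",
            extrinsic=[ExtrinsicTarget("lA1", "lSTG", "forward", b=exp_fwd, tie="exp_fwd")],
        ),
    ]
    return NetworkModel(
        sources=sources, af=af, ab=ab, c=c, modulations=mods, name="two_source"
    )


@pytest.fixture()
def two_source_model():
    return make_two_source_model()


@pytest.fixture(scope="session")
def six_source_model():
    return default_network()


@pytest.fixture(scope="session")
def leadfield8():
    return make_leadfield(8, 2, seed=1)


@pytest.fixture(scope="session")
def leadfield32():
    return make_leadfield(32, 6, seed=0)
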