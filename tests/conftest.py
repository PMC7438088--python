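import numpy as np
import pytest

from cytomech.osmotic import CellParams, ModelConstants, OsmoticProtocol


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def protocol() -> OsmoticProtocol:
    """Standard hyper-then-hypo loading: 333 → 466 → 333 mOsm, 5 min each."""
    return OsmoticProtocol.default()


@pytest.fixture()
def untreated_params() -> CellParams:
    """A cell with the untreated group's mean permeabilities and radius."""
    return CellParams(
        lp=(7.2e-14, 8.8e-14), phi_ir=0.6, radius_ref=9.1e-6, c_ir=333.0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
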