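import numpy as np
import pytest

from dlgnsim.cell import CellParameters, StimulusProtocol


@pytest.fixture(scope="session")
def passive_cell() -> CellParameters:
    """Leak-only cell: g_leak 1.5/0.5 nS, E_leak -76 mV -> Rin 500 MOhm."""
    return CellParameters(
        c_soma=60.0, c_axon=6.0, g_couple=100.0, e_leak=-76.0,
        conductances={"leak": (1.5, 0.5)},
    )


@pytest.fixture(scope="session")
def reference():
    from dlgnsim.reference import reference_cell
    return reference_cell()


@pytest.fixture()
def step_protocol():
    def make(amp_pa: float, dur_ms: float = 800.0, bias: float = 0.0,
             dt: float = 0.025) -> StimulusProtocol:
        return StimulusProtocol(
            "current_clamp",
            [(100.0, 0.0), (dur_ms, amp_pa), (100.0, 0.0)],
            holding_bias=bias, dt=dt,
        )
    return make
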