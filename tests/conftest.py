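import numpy as np
import pytest

from ca1rhythms import cells


@pytest.fixture(scope="session")
def pyr_spec():
    return cells.build_cell("pyr")


@pytest.fixture(scope="session")
def pvbas_spec():
    return cells.build_cell("pvbas")


def make_passive_cell(n_comp: int = 1, g_axial: float = 0.02,
                      e_leak: float = -65.0) -> cells.CellSpec:
    """A leak-only cell (chain of compartments) for fixed-point tests."""
    comps = []
    for i in range(n_comp):
        comps.append(cells.Compartment(
            label="soma" if i == 0 else f"dend{i}",
            depth=0.0 if i == 0 else -100.0 * i,
            length=20.0, diameter=20.0, capacitance=1.0,
            channels=(cells.ChannelDef("leak", 0.1, e_leak, "leak"),),
            axial_conductance_to_parent=0.0 if i == 0 else g_axial,
            parent=None if i == 0 else i - 1))
    return cells.CellSpec(cell_type="pyr" if n_comp >= 4 else "sca",
                          compartments=tuple(comps), spike_threshold=-10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
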