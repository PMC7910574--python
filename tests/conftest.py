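import numpy as np
import pytest

from oasense import (
    PressureLoad,
    SimConfig,
    build_default_geometry,
    probe,
    simulate,
)


@pytest.fixture(scope="session")
def geometry():
    return build_default_geometry()


@pytest.fixture(scope="session")
def config():
    return SimConfig()


@pytest.fixture(scope="session")
def balance_run(geometry, config):
    """One default simulation near the ICP=20 balance point, shared across tests."""
    load = PressureLoad(icp_mmhg=20.0, pio_mmhg=4.0, pe_mmhg=14.0)
    field = simulate(geometry, load, config)
    return {
        "field": field,
        "load": load,
        "probe_ioa": probe(field, geometry, "ioa"),
        "probe_eoa": probe(field, geometry, "eoa"),
    }


@pytest.fixture(scope="session")
def pulsatile_area_cycle(balance_run):
    """Final-cycle IOA/EOA probe area series (mm², 250 samples at 250 Hz)."""
    return (
        balance_run["probe_ioa"].area_mm2.copy(),
        balance_run["probe_eoa"].area_mm2.copy(),
    )
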