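"""Shared fixtures: session-scoped Monte Carlo products at test budgets.

The MC runs are the expensive part of the suite, so Green's functions and
sensitivity maps are computed once per session at reduced photon budgets
(2.5e5 per Green's function; 8e5 for the two separations whose ranking is
compared at 3-mm depth) and shared across test modules.
"""

import numpy as np
import pytest

import difcsim as d
from difcsim import jacobian as J
from difcsim import contrast as C

FIXTURE_SEED = 1234

#: photon budgets per SDS for the NIR sweep; the 1- and 2-mm separations
#: get more photons because their contrast ranking at 3-mm depth is close.
NIR_BUDGETS = {0.3: 400_000, 1.0: 800_000, 2.0: 800_000, 3.0: 400_000, 5.0: 250_000}
BLUE_BUDGETS = {0.3: 250_000, 3.0: 250_000, 6.0: 250_000, 12.0: 250_000}


@pytest.fixture(scope="session")
def volume():
    return d.VoxelVolume()


@pytest.fixture(scope="session")
def maps_780(volume):
    out = {}
    for s, nph in NIR_BUDGETS.items():
        cfg = d.MCConfig(n_photons=nph, seed=FIXTURE_SEED)
        out[s] = J.sensitivity_map("780", s, volume, cfg)
    return out


@pytest.fixture(scope="session")
def maps_488(volume):
    out = {}
    for s, nph in BLUE_BUDGETS.items():
        cfg = d.MCConfig(n_photons=nph, seed=FIXTURE_SEED)
        out[s] = J.sensitivity_map("488", s, volume, cfg)
    return out


@pytest.fixture(scope="session")
def map_640_3(volume):
    cfg = d.MCConfig(n_photons=250_000, seed=FIXTURE_SEED)
    return J.sensitivity_map("640", 3.0, volume, cfg)


@pytest.fixture(scope="session")
def model_nir(maps_780):
    """Detection model calibrated at the NIR phantom anchor (3.5 mm, 0.3-mm SDS)."""
    return C.calibrate_eta_cell(maps_780[0.3], C.DetectionModel(), 3.5)


@pytest.fixture(scope="session")
def curves_780(maps_780, model_nir):
    return {s: C.contrast_curve(m, model_nir) for s, m in maps_780.items()}


@pytest.fixture(scope="session")
def fluence_780(volume):
    """One semi-infinite NIR Green's function kept as a raw fluence field."""
    cfg = d.MCConfig(n_photons=100_000, seed=FIXTURE_SEED)
    src = volume.top_face_center - np.array([0.15, 0.0, 0.0])
    return d.simulate_fluence(volume, "780", src, cfg)


@pytest.fixture(scope="session")
def fluence_488(volume):
    cfg = d.MCConfig(n_photons=100_000, seed=FIXTURE_SEED)
    src = volume.top_face_center - np.array([0.15, 0.0, 0.0])
    return d.simulate_fluence(volume, "488", src, cfg)
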