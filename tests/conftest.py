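"""Shared fixtures: phantoms and solved forward fields, reused across tests."""

import pytest

from iremap import (
    GridSpec,
    PulseProtocol,
    compute_fields,
    lookup_params,
    make_phantom,
    solve_potential,
)


@pytest.fixture(scope="session")
def grid64():
    return GridSpec(n_x=64, n_y=64, fov_mm=30.0)


@pytest.fixture(scope="session")
def homog_phantom(grid64):
    """Two-point homogeneous phantom: 0.3 S/m, 2.2 mm gap, 700 V."""
    return make_phantom(
        grid64, sigma_background=0.3, sigma_tumor=0.3, electrode_gap_mm=2.2, seed=0
    )


@pytest.fixture(scope="session")
def homog_fields(homog_phantom):
    u = solve_potential(homog_phantom.sigma_true, homog_phantom.electrodes)
    e, j = compute_fields(u, homog_phantom.sigma_true)
    return {"u": u, "e": e, "j": j, "phantom": homog_phantom}


@pytest.fixture(scope="session")
def tworegion_phantom(grid64):
    """Tumor 0.4 S/m in 0.2 S/m background, 2.2 mm gap."""
    return make_phantom(
        grid64, sigma_background=0.2, sigma_tumor=0.4, electrode_gap_mm=2.2, seed=0
    )


@pytest.fixture(scope="session")
def tworegion_fields(tworegion_phantom):
    u = solve_potential(tworegion_phantom.sigma_true, tworegion_phantom.electrodes)
    e, j = compute_fields(u, tworegion_phantom.sigma_true)
    return {"u": u, "e": e, "j": j, "phantom": tworegion_phantom}


@pytest.fixture(scope="session")
def pf_params():
    return lookup_params(PulseProtocol())
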