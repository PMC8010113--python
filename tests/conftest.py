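"""Shared fixtures: small synthetic study instances reused across modules."""

import pytest

import silencemap as sm


@pytest.fixture(scope="session")
def small_grid():
    """~120-source symmetric spherical-cap grid with no midline strip."""
    return sm.build_symmetric_grid(120, seed=7)


@pytest.fixture(scope="session")
def strip_grid():
    return sm.build_symmetric_grid(140, strip_width=12.0, seed=3)


@pytest.fixture(scope="session")
def small_montage():
    return sm.build_symmetric_montage(32)


@pytest.fixture(scope="session")
def small_leadfield(small_grid, small_montage):
    return sm.synth_lead_field(small_grid, small_montage)


@pytest.fixture(scope="session")
def small_instance(small_grid, small_leadfield):
    """Simulated recording with a known 8-source silent patch."""
    return sm.simulate_recording(small_grid, small_leadfield, k=8, T=6000,
                                 seed=11, references=("Cz",))


def referenced(sim, ref="Cz"):
    """(Y, A_tilde, differential noise covariance) for one reference."""
    M = sim.schemes[ref].M
    A_t = M @ sim.leadfield.A
    C_z = M @ sim.noise_model.C_z @ M.T
    return sim.recordings[ref].Y, A_t, C_z


@pytest.fixture(scope="session")
def small_referenced(small_instance):
    return referenced(small_instance)
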