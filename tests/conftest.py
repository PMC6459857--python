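"""Shared fixtures: small synthetic streams with known ground truth."""

import numpy as np
import pytest

import mfdlab as m


@pytest.fixture(scope="session")
def confocal():
    return m.ConfocalModel(mean_occupancy=0.02, brightness=120.0,
                           background=0.2)


@pytest.fixture(scope="session")
def single_state_model():
    """One static FRET state at R = R0 (E = 0.5)."""
    st = m.DyeState("s", R_DA=53.0, sigma_DA=0.0, tau_D=4.0, rho=2.0)
    return m.ExchangeModel((st,), np.zeros((1, 1)), R0=53.0)


@pytest.fixture(scope="session")
def single_state_stream(single_state_model, confocal):
    return m.simulate_photon_stream(single_state_model, confocal, 30.0, seed=1)


def two_state_exchange(k_hl, k_lh, r_h=45.0, r_l=52.0, sigma=0.0,
                       tau_d=4.0, rho=2.0):
    hf = m.DyeState("HF", R_DA=r_h, sigma_DA=sigma, tau_D=tau_d, rho=rho)
    lf = m.DyeState("LF", R_DA=r_l, sigma_DA=sigma, tau_D=tau_d, rho=rho)
    Q = np.array([[-k_hl, k_hl], [k_lh, -k_lh]])
    return m.ExchangeModel((hf, lf), Q, R0=53.0)


@pytest.fixture(scope="session")
def slow_two_state_stream(confocal):
    """83/17 mixture of 45/52 Å states in slow (sub-second) exchange."""
    model = two_state_exchange(2.0, 9.7647, sigma=2.0)
    return model, m.simulate_photon_stream(model, confocal, 120.0, seed=42)
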