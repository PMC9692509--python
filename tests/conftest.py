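"""Shared fixtures: expensive flow solutions are session-scoped."""

import numpy as np
import pytest

from nasomag.airflow import FlowParams, solve_flow
from nasomag.geometry import SurrogateParams, build_surrogate, channel_domain


@pytest.fixture(scope="session")
def surrogate_domain():
    return build_surrogate(SurrogateParams())


@pytest.fixture(scope="session")
def surrogate_flow(surrogate_domain):
    return solve_flow(surrogate_domain, FlowParams())


# plane-Poiseuille fixture: Re = rho u W / eta = 20, entrance length ~2 cm
POISEUILLE_WIDTH = 0.01
POISEUILLE_LENGTH = 0.03
POISEUILLE_PARAMS = FlowParams(viscosity=2.85e-4, u_in=0.5)


@pytest.fixture(scope="session")
def channel64_flow():
    dom = channel_domain(length=POISEUILLE_LENGTH, width=POISEUILLE_WIDTH,
                         grid_spacing=POISEUILLE_WIDTH / 64)
    return dom, solve_flow(dom, POISEUILLE_PARAMS)


@pytest.fixture(scope="session")
def channel_coarse_flow():
    """Small, quickly solved channel used by tracing scenarios (air values)."""
    dom = channel_domain(length=0.03, width=0.01, grid_spacing=0.01 / 16)
    return dom, solve_flow(dom, FlowParams(u_in=0.5))
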