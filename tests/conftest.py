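"""Shared fixtures: the toy coculture, its community model, and hand optima.

All expected values asserted against these fixtures come from hand linear
algebra on the frozen toy stoichiometry (documented in
``comgem.fixtures``); the LP implementation is cross-checked against
cobra/GLPK as an independent solver route where noted.
"""

import pytest

import comgem as cg

# hand linear-algebra optima for the coculture under the measured-rate
# constraint set (net O2 exchange closed, net CO2 uptake fixed at 0.680)
MU_STAR = 0.680 * 97.0 / 1800.0  # ammonium-mode community growth rate, 1/hr
X_M_STAR = 45.0 / 97.0
X_C_STAR = 52.0 / 97.0
MU_MODE_B = 0.680 * 101.0 / 1980.0  # forced-nitrate mode
CH4_UPTAKE_STAR = 0.680  # mmol/gDCW/hr (community basis)
NH4_CROSSFEED_STAR = 8.0 * MU_STAR * X_M_STAR

#: community exchange bounds emulating the measured-rate constraint set
MEASURED_BOUNDS = {
    "o2": (0.0, 0.0),
    "co2": (-0.680, -0.680),
    "nh4": (0.0, 1000.0),  # no ammonium in the medium; secretion allowed
}


@pytest.fixture(scope="session")
def toy_pair():
    return cg.fixtures.make_toybin1()


@pytest.fixture(scope="session")
def toy_policy():
    return cg.ExchangePolicy(
        whitelist=("ch4", "o2", "co2", "photon", "nh4", "no3"),
        bounds=MEASURED_BOUNDS,
    )


@pytest.fixture(scope="session")
def toy_community(toy_pair, toy_policy):
    """Community with the measured-rate exchange bounds baked in."""
    m, c = toy_pair
    return cg.build_community(cg.harmonize_ids([m, c]), toy_policy)


@pytest.fixture(scope="session")
def open_community(toy_pair):
    """Community with open gas exchange (only ammonium excluded from the
    medium), as used for trajectory-driven solves."""
    m, c = toy_pair
    policy = cg.ExchangePolicy(
        whitelist=("ch4", "o2", "co2", "photon", "nh4", "no3"),
        bounds={"nh4": (0.0, 1000.0)},
    )
    return cg.build_community(cg.harmonize_ids([m, c]), policy)


@pytest.fixture(scope="session")
def steadycom_solution(toy_community):
    return cg.solve_steadycom(toy_community)
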