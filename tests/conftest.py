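import logging

import numpy as np
import pytest

import exmort as em

# exclusion notices from the Bayes likelihood are expected in many tests
logging.getLogger("exmort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dementia():
    return em.dementia_scenario()


@pytest.fixture(scope="session")
def constant_world():
    """Constant incidence 0.01, no excess mortality: p(a) = 1 - exp(-0.01 a)."""
    return em.Scenario(
        incidence=em.ConstantRate(0.01),
        m0=em.GompertzMakehamMortality(-10.7, 0.1, 1.0),
        ratio=em.LogLinearRateRatio(60.0, 1.0, 95.0, 1.0),
        time_origin=2000.0,
    )


@pytest.fixture(scope="session")
def diabetes_world():
    """Diabetes-like scenario with known truth (R(50), R(90)) = (4.5, 1.4).

    Returns the scenario, its exact initial (2009) and target (2015)
    cross-sections, and the implied general-mortality surface.
    """
    scen, initial = em.diabetes_like_scenario(4.5, 1.4)
    target = em.cross_section(scen, 2015.0, initial.ages, method="odds")
    gm = em.ScenarioGeneralMortality(scen)
    return scen, initial, target, gm


@pytest.fixture(scope="session")
def diabetes_data(diabetes_world):
    scen, initial, target, gm = diabetes_world
    return em.BayesData(
        initial_cs=initial,
        target_cs=target.with_group_sizes(1e6),
        incidence=scen.incidence,
        general_mortality=gm,
    )


@pytest.fixture(scope="session")
def dementia_sweep(dementia):
    """Exact dementia cross-sections and direct estimates over a ΔT sweep."""
    ages = np.arange(65.0, 96.0, 5.0)
    out = {}
    for dt in (0.1, 0.5, 1.0, 3.0, 5.0, 10.0):
        cs1 = em.cross_section(dementia, 2000.0 - dt / 2, ages - dt / 2, method="odds")
        cs2 = em.cross_section(dementia, 2000.0 + dt / 2, ages + dt / 2, method="odds")
        res = em.ExcessMortalityModel(
            cs1,
            cs2,
            incidence=lambda a: dementia.incidence_at(2000.0, a),
            m0=lambda a: dementia.m0_at(2000.0, a),
        ).fit(ages=ages)
        out[dt] = res
    return ages, out
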