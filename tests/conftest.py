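import dataclasses
import warnings

import pytest
from hypothesis import settings as hypothesis_settings

import flukemr as fm

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def strata():
    return fm.default_strata()


@pytest.fixture(scope="session")
def small_sim():
    """A quarter-scale 2003-2010 simulation shared across tests.

    Small enough to keep the suite fast, large enough that every stratum
    cell is populated in most years.
    """
    base = fm.SimConfig()
    config = dataclasses.replace(
        base,
        start_year=2003,
        end_year=2010,
        initial_abundance={k: v // 4 for k, v in base.initial_abundance.items()},
        seed=20240801,
    )
    return fm.simulate(config)


@pytest.fixture(scope="session")
def small_captures(small_sim, strata):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        captures, report = fm.condense(small_sim.encounters, strata)
    return captures


@pytest.fixture(scope="session")
def small_reference(small_sim, strata):
    return fm.splash_like_reference(small_sim, strata, mid_year=2005)
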