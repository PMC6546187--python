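import dataclasses

import pytest

from rosscea import SimulationProfile, generate_cohorts, generate_input_deck


@pytest.fixture(scope="session")
def deck():
    """The shipped placeholder input deck."""
    return generate_input_deck()


@pytest.fixture(scope="session")
def uncertain_deck(deck):
    """Synthetic stress deck with genuine decision uncertainty.

    The shipped deck's survival advantage makes the Ross strategy dominant
    in essentially every draw, which degenerates value-of-information
    quantities to 0.  Raising the Ross late-mortality point estimate into
    the conventional-AVR range produces closely matched strategies, so
    EVPI/EVPPI are strictly positive and the estimators can be compared
    non-trivially.  Synthetic: not a published parameterisation.
    """
    return deck.with_value("rate.ross.total_mortality", 1.55)


@pytest.fixture(scope="session")
def small_deck(deck):
    """Shipped deck truncated to an 11-cycle horizon for microsim checks."""
    return dataclasses.replace(deck, params=dict(deck.params), horizon=10)


@pytest.fixture(scope="session")
def cohorts():
    """One synthetic evidence base under the default profile."""
    return generate_cohorts(SimulationProfile(seed=1))
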