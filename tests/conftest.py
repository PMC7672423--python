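import pytest

import hairpinjoint as hj


@pytest.fixture(scope="session")
def fixture_set():
    """Seeded synthetic 22-nt triggers and 20-nt spacers (the regression set)."""
    return hj.generate_fixtures(42, length_bounds=(22, 22))


@pytest.fixture(scope="session")
def circuit(fixture_set):
    """One deterministic valid circuit from the first fixture pair."""
    trigger = fixture_set.triggers[0][1]
    spacer = fixture_set.spacers[0][1]
    return hj.design_circuit(trigger, spacer, hj.DesignParams(rng_seed=0))
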